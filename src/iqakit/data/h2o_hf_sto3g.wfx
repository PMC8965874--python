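<Title>
 H2O RHF/STO-3G TIP3P geometry
</Title>
<Keywords>
 GTO
</Keywords>
<Number of Nuclei>
 3
</Number of Nuclei>
<Number of Occupied Molecular Orbitals>
 5
</Number of Occupied Molecular Orbitals>
<Number of Perturbations>
 0
</Number of Perturbations>
<Number of Electrons>
 10
</Number of Electrons>
<Charge>
 0
</Charge>
<Electronic Spin Multiplicity>
 1
</Electronic Spin Multiplicity>
<Nuclear Names>
 O1
 H2
 H3
</Nuclear Names>
<Atomic Numbers>
 8
 1
 1
</Atomic Numbers>
<Nuclear Charges>
 8.0000000000E+00
 1.0000000000E+00
 1.0000000000E+00
</Nuclear Charges>
<Nuclear Cartesian Coordinates>
  0.000000000000E+00  0.000000000000E+00  0.000000000000E+00
  1.430429378570E+00  0.000000000000E+00  1.107157485337E+00
 -1.430429378570E+00  0.000000000000E+00  1.107157485337E+00
</Nuclear Cartesian Coordinates>
<Number of Primitives>
 21
</Number of Primitives>
<Primitive Centers>
 1 1 1 1 1 1 1 1 1 1
 1 1 1 1 1 2 2 2 3 3
 3
</Primitive Centers>
<Primitive Types>
 1 1 1 1 1 1 2 2 2 3
 3 3 4 4 4 1 1 1 1 1
 1
</Primitive Types>
<Primitive Exponents>
  1.307093214000E+02  2.380886605000E+01  6.443608310000E+00  5.033151320000E+00
  1.169596120000E+00  3.803889600000E-01  5.033151320000E+00  1.169596120000E+00
  3.803889600000E-01  5.033151320000E+00  1.169596120000E+00  3.803889600000E-01
  5.033151320000E+00  1.169596120000E+00  3.803889600000E-01  3.425250910000E+00
  6.239137300000E-01  1.688554000000E-01  3.425250910000E+00  6.239137300000E-01
  1.688554000000E-01
</Primitive Exponents>
<Molecular Orbital Occupation Numbers>
 2.000000000000E+00
 2.000000000000E+00
 2.000000000000E+00
 2.000000000000E+00
 2.000000000000E+00
</Molecular Orbital Occupation Numbers>
<Molecular Orbital Energies>
 -2.024173897141E+01
 -1.268408866724E+00
 -6.179341284364E-01
 -4.529944616151E-01
 -3.912446701875E-01
</Molecular Orbital Energies>
<Molecular Orbital Spin Types>
 Alpha and Beta
 Alpha and Beta
 Alpha and Beta
 Alpha and Beta
 Alpha and Beta
</Molecular Orbital Spin Types>
<Molecular Orbital Primitive Coefficients>
<MO Number>
 1
</MO Number>
  4.226982141740E+00  4.088153011048E+00  1.274098726150E+00 -6.359386214227E-03
  8.506192799284E-03  6.419750564111E-03  1.354323178518E-16  8.516347824132E-17
  1.349132571286E-17 -1.184430773217E-16 -7.448018758242E-17 -1.179891299158E-17
  7.282174862489E-03  4.579227102424E-03  7.254265047384E-04 -1.653872031138E-03
 -1.599552992420E-03 -4.985107916583E-04 -1.653872031138E-03 -1.599552992420E-03
 -4.985107916583E-04
<MO Number>
 2
</MO Number>
 -9.897919327404E-01 -9.572836445623E-01 -2.983434985933E-01 -1.995486674381E-01
  2.669124630725E-01  2.014428165233E-01 -5.100408931565E-16 -3.207274097904E-16
 -5.080860998025E-17 -1.061611442397E-16 -6.675697825259E-17 -1.057542688264E-17
  2.171375279584E-01  1.365419083936E-01  2.163053221446E-02  4.395545031228E-02
  4.251179701720E-02  1.324907001287E-02  4.395545031228E-02  4.251179701720E-02
  1.324907001287E-02
<MO Number>
 3
</MO Number>
 -1.725313867615E-15 -1.668648422535E-15 -5.200448280183E-16 -4.346907256037E-16
  5.814339616256E-16  4.388168821490E-16 -1.016065811336E+00 -6.389294666742E-01
 -1.012171616338E-01 -5.169308549445E-16 -3.250600027794E-16 -5.149496549794E-17
 -2.921358343128E-15 -1.837028573655E-15 -2.910161884274E-16 -1.232360949801E-01
 -1.191885833899E-01 -3.714587471869E-02  1.232360949801E-01  1.191885833899E-01
  3.714587471869E-02
<MO Number>
 4
</MO Number>
 -4.386981789316E-01 -4.242897701012E-01 -1.322325886882E-01 -1.285315708324E-01
  1.719213593049E-01  1.297516138446E-01  3.134291077491E-15  1.970926394924E-15
  3.122278528203E-16  4.802580216326E-15  3.019991404141E-15  4.784173747325E-16
 -1.301396397147E+00 -8.183530010393E-01 -1.296408638200E-01 -7.693996961092E-02
 -7.441298740819E-02 -2.319127746209E-02 -7.693996961092E-02 -7.441298740819E-02
 -2.319127746209E-02
<MO Number>
 5
</MO Number>
  1.144683024956E-15  1.107087562296E-15  3.450308364306E-16  3.235186594579E-16
 -4.327323422122E-16 -3.265895522918E-16 -1.423231989426E-16 -8.949664931265E-17
 -1.417777280850E-17  1.675450149140E+00  1.053568044791E+00  1.669028783990E-01
  3.668239262322E-15  2.306687351704E-15  3.654180292096E-16  1.213258471626E-16
  1.173410749036E-16  3.657008703146E-17  2.394474589227E-16  2.315831528898E-16
  7.217435210268E-17
</Molecular Orbital Primitive Coefficients>
<Energy = T + Vne + Vee + Vnn>
 -7.496292831032E+01
</Energy = T + Vne + Vee + Vnn>
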