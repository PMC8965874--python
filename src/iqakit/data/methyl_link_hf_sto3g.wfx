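<Title>
 CH3 + H-link RHF/STO-3G (ethane QM/MM cut)
</Title>
<Keywords>
 GTO
</Keywords>
<Number of Nuclei>
 5
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
 C1
 H2
 H3
 H4
 H5
</Nuclear Names>
<Atomic Numbers>
 6
 1
 1
 1
 1
</Atomic Numbers>
<Nuclear Charges>
 6.0000000000E+00
 1.0000000000E+00
 1.0000000000E+00
 1.0000000000E+00
 1.0000000000E+00
</Nuclear Charges>
<Nuclear Cartesian Coordinates>
  0.000000000000E+00  0.000000000000E+00  0.000000000000E+00
  1.942014856234E+00  0.000000000000E+00 -6.865593928863E-01
 -9.710074281172E-01  1.681834200026E+00 -6.865593928863E-01
 -9.710074281172E-01 -1.681834200026E+00 -6.865593928863E-01
  0.000000000000E+00  0.000000000000E+00  2.059802296774E+00
</Nuclear Cartesian Coordinates>
<Number of Primitives>
 27
</Number of Primitives>
<Primitive Centers>
 1 1 1 1 1 1 1 1 1 1
 1 1 1 1 1 2 2 2 3 3
 3 4 4 4 5 5 5
</Primitive Centers>
<Primitive Types>
 1 1 1 1 1 1 2 2 2 3
 3 3 4 4 4 1 1 1 1 1
 1 1 1 1 1 1 1
</Primitive Types>
<Primitive Exponents>
  7.161683735000E+01  1.304509632000E+01  3.530512160000E+00  2.941249400000E+00
  6.834831000000E-01  2.222899000000E-01  2.941249400000E+00  6.834831000000E-01
  2.222899000000E-01  2.941249400000E+00  6.834831000000E-01  2.222899000000E-01
  2.941249400000E+00  6.834831000000E-01  2.222899000000E-01  3.425250910000E+00
  6.239137300000E-01  1.688554000000E-01  3.425250910000E+00  6.239137300000E-01
  1.688554000000E-01  3.425250910000E+00  6.239137300000E-01  1.688554000000E-01
  3.425250910000E+00  6.239137300000E-01  1.688554000000E-01
</Primitive Exponents>
<Molecular Orbital Occupation Numbers>
 2.000000000000E+00
 2.000000000000E+00
 2.000000000000E+00
 2.000000000000E+00
 2.000000000000E+00
</Molecular Orbital Occupation Numbers>
<Molecular Orbital Energies>
 -1.103030961868E+01
 -9.084900854635E-01
 -5.177452863023E-01
 -5.177452863023E-01
 -5.177381309599E-01
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
  2.686039020709E+00  2.597819944119E+00  8.096270061783E-01 -6.085323890657E-03
  8.139612267485E-03  6.143086397004E-03 -5.154128973521E-17 -3.241054680188E-17
 -5.134374596382E-18 -1.084737937706E-16 -6.821123390277E-17 -1.080580431670E-17
  2.180746781355E-07  1.371312126322E-07  2.172388570960E-08 -1.917072822148E-03
 -1.854109333504E-03 -5.778448829431E-04 -1.917072822148E-03 -1.854109333504E-03
 -5.778448829431E-04 -1.917072822148E-03 -1.854109333504E-03 -5.778448829431E-04
 -1.917087890964E-03 -1.854123907405E-03 -5.778494249916E-04
<MO Number>
 2
</MO Number>
  5.988779441188E-01  5.792086620222E-01  1.805140406468E-01  1.007365491266E-01
 -1.347432718108E-01 -1.016927505816E-01 -8.646683009247E-16 -5.437266428372E-16
 -8.613542620631E-17 -4.135761972641E-16 -2.600678168210E-16 -4.119910719756E-17
 -4.812592134633E-06 -3.026287146077E-06 -4.794146775479E-07 -5.005976811493E-02
 -4.841562731609E-02 -1.508903600966E-02 -5.005976811493E-02 -4.841562731609E-02
 -1.508903600966E-02 -5.005976811493E-02 -4.841562731609E-02 -1.508903600966E-02
 -5.006010219476E-02 -4.841595042354E-02 -1.508913670814E-02
<MO Number>
 3
</MO Number>
  8.586234837045E-17  8.304232340850E-17  2.588066499356E-17  1.030877108767E-16
 -1.378881405749E-16 -1.040662297954E-16 -4.811281413739E-01 -3.025462929588E-01
 -4.792841078222E-02 -8.683274238666E-02 -5.460275975858E-02 -8.649993605801E-03
  3.019385787023E-11  1.898670849449E-11  3.007813300989E-12 -1.341978108916E-01
 -1.297902775707E-01 -4.044995966245E-02  4.612405751613E-02  4.460917944884E-02
  1.390273249318E-02  8.807375336655E-02  8.518109811323E-02  2.654722716658E-02
  8.932730250938E-12  8.639347624455E-12  2.692507246767E-12
<MO Number>
 4
</MO Number>
  2.330278270125E-16  2.253743642145E-16  7.023934517920E-17  5.950798703865E-17
 -7.959673963399E-17 -6.007284283610E-17 -8.683274238666E-02 -5.460275975858E-02
 -8.649993605801E-03  4.811281413739E-01  3.025462929588E-01  4.792841078222E-02
  1.698009083405E-11  1.067753700974E-11  1.691501075555E-12 -2.421966819334E-02
 -2.342420816404E-02 -7.300302403961E-03  1.283285474560E-01  1.241137816176E-01
  3.868084385018E-02 -1.041088792677E-01 -1.006895734584E-01 -3.138054144774E-02
  5.023495195034E-12  4.858505749138E-12  1.514183999378E-12
<MO Number>
 5
</MO Number>
  7.738104523716E-06  7.483957644098E-06  2.332422705228E-06  1.684618521326E-06
 -2.253313353341E-06 -1.700609089746E-06  3.272930092473E-11  2.058106316050E-11
  3.260385839948E-12 -1.134742350960E-11 -7.135564566353E-12 -1.130393191583E-12
  4.889039752070E-01  3.074359460440E-01  4.870301389953E-02 -4.821294078620E-02
 -4.662945636420E-02 -1.453236455239E-02 -4.821294080263E-02 -4.662945638009E-02
 -1.453236455735E-02 -4.821294079715E-02 -4.662945637479E-02 -1.453236455569E-02
  1.446386878645E-01  1.398882390157E-01  4.359705311791E-02
</Molecular Orbital Primitive Coefficients>
<Energy = T + Vne + Vee + Vnn>
 -3.972670003110E+01
</Energy = T + Vne + Vee + Vnn>
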