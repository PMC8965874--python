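<Title>
 H2O RHF/STO-3G embedded in 2 TIP3P point-charge waters
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
 -2.023359155907E+01
 -1.254676058200E+00
 -6.056311511273E-01
 -4.368071357459E-01
 -3.733650986082E-01
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
  4.227030228007E+00  4.088199517992E+00  1.274113220333E+00 -6.348471944558E-03
  8.491594081901E-03  6.408732694382E-03  2.017925604004E-16  1.268925807334E-16
  2.010191660290E-17 -1.175875996085E-16 -7.394224022412E-17 -1.171369309242E-17
  7.325631524831E-03  4.606553818650E-03  7.297555156817E-04 -1.653099767740E-03
 -1.598806092898E-03 -4.982780157056E-04 -1.653099767740E-03 -1.598806092898E-03
 -4.982780157056E-04
<MO Number>
 2
</MO Number>
 -9.865064930930E-01 -9.541061104406E-01 -2.973531999998E-01 -1.985932123116E-01
  2.656344646552E-01  2.004782920581E-01 -5.998129640023E-16 -3.771784985956E-16
 -5.975141083391E-17  2.290094378896E-16  1.440072841559E-16  2.281317315465E-17
  2.241416642860E-01  1.409462973991E-01  2.232826142733E-02  4.459727096556E-02
  4.313253799789E-02  1.344252785963E-02  4.459727096556E-02  4.313253799789E-02
  1.344252785963E-02
<MO Number>
 3
</MO Number>
 -8.105886783832E-16 -7.839660625796E-16 -2.443279786686E-16 -1.955547105683E-16
  2.615702231107E-16  1.974109483517E-16 -1.006449123611E+00 -6.328822351946E-01
 -1.002591785730E-01 -2.593082361763E-15 -1.630599821348E-15 -2.583144060275E-16
 -1.172650577766E-15 -7.373941725898E-16 -1.168156252729E-16 -1.245774450613E-01
 -1.204858787646E-01 -3.755018501495E-02  1.245774450613E-01  1.204858787646E-01
  3.755018501495E-02
<MO Number>
 4
</MO Number>
  4.482279653283E-01  4.335065644112E-01  1.351050608921E-01  1.311176165174E-01
 -1.753804043202E-01 -1.323622067047E-01 -1.273655835692E-15 -8.009089910766E-16
 -1.268774395799E-16  6.735390055423E-15  4.235394132879E-15  6.709575859162E-16
  1.291984772809E+00  8.124347189246E-01  1.287033085050E-01  7.809252208129E-02
  7.552768595692E-02  2.353868030439E-02  7.809252208129E-02  7.552768595692E-02
  2.353868030439E-02
<MO Number>
 5
</MO Number>
 -1.765245339650E-15 -1.707268402975E-15 -5.320809890302E-16 -5.355442082513E-16
  7.163336420320E-16  5.406276828000E-16 -9.383370598166E-16 -5.900515404614E-16
 -9.347407696505E-17  1.675450149140E+00  1.053568044791E+00  1.669028783990E-01
 -4.601753958299E-15 -2.893706460288E-15 -4.584117180199E-16 -5.208008174722E-16
 -5.036958666440E-16 -1.569799978029E-16 -1.639595381334E-16 -1.585745238564E-16
 -4.942075179697E-17
</Molecular Orbital Primitive Coefficients>
<Energy = T + Vne + Vee + Vnn>
 -7.495341411747E+01
</Energy = T + Vne + Vee + Vnn>
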