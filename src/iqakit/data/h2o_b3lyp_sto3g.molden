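[Molden Format]
[Title]
 H2O B3LYP/STO-3G TIP3P geometry
[Atoms] AU
 O      1    8  0.0000000000  0.0000000000  0.0000000000
 H      2    1  1.4304293786  0.0000000000  1.1071574853
 H      3    1 -1.4304293786  0.0000000000  1.1071574853
[GTO]
 1 0
 s 3 1.00
   1.3070932140E+02  1.5432897000E-01
   2.3808866050E+01  5.3532814000E-01
   6.4436083100E+00  4.4463454000E-01
 s 3 1.00
   5.0331513200E+00 -9.9967230000E-02
   1.1695961200E+00  3.9951283000E-01
   3.8038896000E-01  7.0011547000E-01
 p 3 1.00
   5.0331513200E+00  1.5591627000E-01
   1.1695961200E+00  6.0768372000E-01
   3.8038896000E-01  3.9195739000E-01

 2 0
 s 3 1.00
   3.4252509100E+00  1.5432897000E-01
   6.2391373000E-01  5.3532814000E-01
   1.6885540000E-01  4.4463454000E-01

 3 0
 s 3 1.00
   3.4252509100E+00  1.5432897000E-01
   6.2391373000E-01  5.3532814000E-01
   1.6885540000E-01  4.4463454000E-01

[MO]
 Sym= A
 Ene= -1.8831176895E+01
 Spin= Alpha
 Occup= 2.00000000
    1  -9.933949548948E-01
    2  -2.999307185458E-02
    3  -1.024161103851E-17
    4   6.643882167700E-17
    5  -4.845839490056E-03
    6   7.214634714338E-03
    7   7.214634714338E-03
 Sym= A
 Ene= -9.3200648467E-01
 Spin= Alpha
 Occup= 2.00000000
    1  -2.272609017818E-01
    2   7.981504588291E-01
    3  -1.502776591446E-15
    4   5.832278931653E-17
    5   1.902775762297E-01
    6   1.732312727273E-01
    7   1.732312727273E-01
 Sym= A
 Ene= -4.4022397857E-01
 Spin= Alpha
 Occup= 2.00000000
    1  -2.181915598646E-16
    2   4.330802601543E-16
    3   6.075997007787E-01
    4   1.070449992810E-16
    5   9.150106842228E-16
    6   4.440215257653E-01
    7  -4.440215257653E-01
 Sym= A
 Ene= -2.2669875456E-01
 Spin= Alpha
 Occup= 2.00000000
    1   1.227115194740E-01
    2  -6.072505277143E-01
    3  -2.897080127778E-15
    4   1.079386290884E-15
    5   7.555176663902E-01
    6   2.760893727061E-01
    7   2.760893727061E-01
 Sym= A
 Ene= -1.4049800556E-01
 Spin= Alpha
 Occup= 2.00000000
    1  -1.265994757419E-16
    2   6.571283072658E-16
    3  -5.529836045984E-17
    4   1.000000003790E+00
    5  -5.708004006628E-16
    6  -4.409452531499E-16
    7  -2.340574417145E-16
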