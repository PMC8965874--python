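[Molden Format]
[Title]
 H2O RHF/STO-3G TIP3P geometry
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
 Ene= -2.0241738971E+01
 Spin= Alpha
 Occup= 2.00000000
    1   9.941294583510E-01
    2   2.656240901822E-02
    3   8.083339181093E-17
    4  -7.069328671548E-17
    5   4.346399022273E-03
    6  -5.972072345888E-03
    7  -5.972072345888E-03
 Sym= A
 Ene= -1.2684088667E+00
 Spin= Alpha
 Occup= 2.00000000
    1  -2.327857759935E-01
    2   8.334913378392E-01
    3  -3.044202152785E-16
    4  -6.336275937338E-17
    5   1.295995162213E-01
    6   1.587215481723E-01
    7   1.587215481723E-01
 Sym= A
 Ene= -6.1793412844E-01
 Spin= Alpha
 Occup= 2.00000000
    1  -4.057706617119E-16
    2   1.815652086687E-15
    3  -6.064434777179E-01
    4  -3.085325201523E-16
    5  -1.743625947749E-15
    6  -4.450011010462E-01
    7   4.450011010462E-01
 Sym= A
 Ene= -4.5299446162E-01
 Spin= Alpha
 Occup= 2.00000000
    1  -1.031759227687E-01
    2   5.368612694989E-01
    3   1.870715813884E-15
    4   2.866441736266E-15
    5  -7.767443291269E-01
    6  -2.778274595349E-01
    7  -2.778274595349E-01
 Sym= A
 Ene= -3.9124467019E-01
 Spin= Alpha
 Occup= 2.00000000
    1   2.692140816839E-16
    2  -1.351299428602E-15
    3  -8.494624537476E-17
    4   1.000000003790E+00
    5   2.189405204391E-15
    6   4.381032649681E-16
    7   8.646361512878E-16
 Sym= A
 Ene=  6.0567346912E-01
 Spin= Alpha
 Occup= 0.00000000
    1   1.323914081490E-01
    2  -8.847618331099E-01
    3   9.757816842822E-15
    4  -5.152241709997E-17
    5  -7.423143910084E-01
    6   7.971621060433E-01
    7   7.971621060433E-01
 Sym= A
 Ene=  7.4239864054E-01
 Spin= Alpha
 Occup= 0.00000000
    1  -1.182431574644E-15
    2   8.424756523365E-15
    3   9.906030238199E-01
    4   2.330293153231E-17
    5   7.351430213074E-15
    6  -8.386989290364E-01
    7   8.386989290364E-01
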