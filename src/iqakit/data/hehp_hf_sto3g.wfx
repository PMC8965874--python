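<Title>
 HeH+ RHF/STO-3G R=1.4632 bohr
</Title>
<Keywords>
 GTO
</Keywords>
<Number of Nuclei>
 2
</Number of Nuclei>
<Number of Occupied Molecular Orbitals>
 1
</Number of Occupied Molecular Orbitals>
<Number of Perturbations>
 0
</Number of Perturbations>
<Number of Electrons>
 2
</Number of Electrons>
<Charge>
 1
</Charge>
<Electronic Spin Multiplicity>
 1
</Electronic Spin Multiplicity>
<Nuclear Names>
 He1
 H2
</Nuclear Names>
<Atomic Numbers>
 2
 1
</Atomic Numbers>
<Nuclear Charges>
 2.0000000000E+00
 1.0000000000E+00
</Nuclear Charges>
<Nuclear Cartesian Coordinates>
  0.000000000000E+00  0.000000000000E+00  0.000000000000E+00
  0.000000000000E+00  0.000000000000E+00  1.463200000000E+00
</Nuclear Cartesian Coordinates>
<Number of Primitives>
 6
</Number of Primitives>
<Primitive Centers>
 1 1 1 2 2 2
</Primitive Centers>
<Primitive Types>
 1 1 1 1 1 1
</Primitive Types>
<Primitive Exponents>
  6.362421390000E+00  1.158923000000E+00  3.136497900000E-01  3.425250910000E+00
  6.239137300000E-01  1.688554000000E-01
</Primitive Exponents>
<Molecular Orbital Occupation Numbers>
 2.000000000000E+00
</Molecular Orbital Occupation Numbers>
<Molecular Orbital Energies>
 -1.632802490584E+00
</Molecular Orbital Energies>
<Molecular Orbital Spin Types>
 Alpha and Beta
</Molecular Orbital Spin Types>
<Molecular Orbital Primitive Coefficients>
<MO Number>
 1
</MO Number>
 -3.862583060829E-01 -3.735722097024E-01 -1.164261399866E-01 -5.607407542450E-02
 -5.423240338656E-02 -1.690187100639E-02
</Molecular Orbital Primitive Coefficients>
<Energy = T + Vne + Vee + Vnn>
 -2.841836499287E+00
</Energy = T + Vne + Vee + Vnn>
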