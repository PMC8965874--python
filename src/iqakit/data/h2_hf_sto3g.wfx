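<Title>
 H2 RHF/STO-3G R=1.4 bohr
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
 0
</Charge>
<Electronic Spin Multiplicity>
 1
</Electronic Spin Multiplicity>
<Nuclear Names>
 H1
 H2
</Nuclear Names>
<Atomic Numbers>
 1
 1
</Atomic Numbers>
<Nuclear Charges>
 1.0000000000E+00
 1.0000000000E+00
</Nuclear Charges>
<Nuclear Cartesian Coordinates>
  0.000000000000E+00  0.000000000000E+00  0.000000000000E+00
  0.000000000000E+00  0.000000000000E+00  1.400000000000E+00
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
  3.425250910000E+00  6.239137300000E-01  1.688554000000E-01  3.425250910000E+00
  6.239137300000E-01  1.688554000000E-01
</Primitive Exponents>
<Molecular Orbital Occupation Numbers>
 2.000000000000E+00
</Molecular Orbital Occupation Numbers>
<Molecular Orbital Energies>
 -5.782029775125E-01
</Molecular Orbital Energies>
<Molecular Orbital Spin Types>
 Alpha and Beta
</Molecular Orbital Spin Types>
<Molecular Orbital Primitive Coefficients>
<MO Number>
 1
</MO Number>
  1.520186976832E-01  1.470258630685E-01  4.582153872980E-02  1.520186976832E-01
  1.470258630685E-01  4.582153872980E-02
</Molecular Orbital Primitive Coefficients>
<Energy = T + Vne + Vee + Vnn>
 -1.116714325063E+00
</Energy = T + Vne + Vee + Vnn>
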