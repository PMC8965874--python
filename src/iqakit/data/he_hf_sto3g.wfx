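<Title>
 He RHF/STO-3G
</Title>
<Keywords>
 GTO
</Keywords>
<Number of Nuclei>
 1
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
 He1
</Nuclear Names>
<Atomic Numbers>
 2
</Atomic Numbers>
<Nuclear Charges>
 2.0000000000E+00
</Nuclear Charges>
<Nuclear Cartesian Coordinates>
  0.000000000000E+00  0.000000000000E+00  0.000000000000E+00
</Nuclear Cartesian Coordinates>
<Number of Primitives>
 3
</Number of Primitives>
<Primitive Centers>
 1 1 1
</Primitive Centers>
<Primitive Types>
 1 1 1
</Primitive Types>
<Primitive Exponents>
  6.362421390000E+00  1.158923000000E+00  3.136497900000E-01
</Primitive Exponents>
<Molecular Orbital Occupation Numbers>
 2.000000000000E+00
</Molecular Orbital Occupation Numbers>
<Molecular Orbital Energies>
 -8.760355074025E-01
</Molecular Orbital Energies>
<Molecular Orbital Spin Types>
 Alpha and Beta
</Molecular Orbital Spin Types>
<Molecular Orbital Primitive Coefficients>
<MO Number>
 1
</MO Number>
  4.406303153781E-01  4.261584488549E-01  1.328149737433E-01
</Molecular Orbital Primitive Coefficients>
<Energy = T + Vne + Vee + Vnn>
 -2.807783957540E+00
</Energy = T + Vne + Vee + Vnn>
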