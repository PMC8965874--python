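%VERSION  VERSION_STAMP = V0001.000  DATE = 01/01/24
%FLAG TITLE
%FORMAT(20a4)
TIP3P water
%FLAG POINTERS
%FORMAT(10I8)
       3       2       2       0       1       0       0       0       0       0
       0       1       0       0       0       1       1       0       0       0
       0       0       0       0       0       0       0       0       0       0
       0
%FLAG ATOM_NAME
%FORMAT(20a4)
O   H1  H2  
%FLAG CHARGE
%FORMAT(5E16.8)
 -1.51973982E+01  7.59869910E+00  7.59869910E+00
%FLAG ATOMIC_NUMBER
%FORMAT(10I8)
       8       1       1
%FLAG MASS
%FORMAT(5E16.8)
  1.60000000E+01  1.00800000E+00  1.00800000E+00
%FLAG ATOM_TYPE_INDEX
%FORMAT(10I8)
       1       2       2
%FLAG NUMBER_EXCLUDED_ATOMS
%FORMAT(10I8)
       2       1       1
%FLAG NONBONDED_PARM_INDEX
%FORMAT(10I8)
       1       2       2       3
%FLAG LENNARD_JONES_ACOEF
%FORMAT(5E16.8)
  5.81935564E+05  0.00000000E+00  0.00000000E+00
%FLAG LENNARD_JONES_BCOEF
%FORMAT(5E16.8)
  5.94825035E+02  0.00000000E+00  0.00000000E+00
%FLAG BONDS_INC_HYDROGEN
%FORMAT(10I8)
       0       3       1       0       6       1
%FLAG BOND_FORCE_CONSTANT
%FORMAT(5E16.8)
  4.50000000E+02
%FLAG BOND_EQUIL_VALUE
%FORMAT(5E16.8)
  9.57200000E-01
%FLAG ANGLES_INC_HYDROGEN
%FORMAT(10I8)
       3       0       6       1
%FLAG ANGLE_FORCE_CONSTANT
%FORMAT(5E16.8)
  5.50000000E+01
%FLAG ANGLE_EQUIL_VALUE
%FORMAT(5E16.8)
  1.82421813E+00
%FLAG EXCLUDED_ATOMS_LIST
%FORMAT(10I8)
       2       3       3       0
%FLAG SCEE_SCALE_FACTOR
%FORMAT(5E16.8)
  1.20000000E+00
%FLAG SCNB_SCALE_FACTOR
%FORMAT(5E16.8)
  2.00000000E+00
%FLAG RADII
%FORMAT(5E16.8)
  1.52000000E+00  1.20000000E+00  1.20000000E+00
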