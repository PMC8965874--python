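{
  "_comment": [
    "Reference energy components for a homologous series of",
    "hydroxamate-sulfonamide inhibitors bound to the MMP-12 catalytic",
    "domain, from published QM/MM-PBSA calculations on partially relaxed",
    "crystal structures (kcal/mol).  'binding' holds the Coulombic and",
    "vdW QM/MM energy changes and the PBSA solvation change on binding;",
    "'fragments' holds the IQF components of the three inhibitor moieties",
    "(ZBG zinc-binding group, NSO sulfonamide, BZ benzene tail):",
    "electron-population change dq (e), fragment net-energy change de_net,",
    "fragment solvation change dg_solv, and half the fragment interaction",
    "change half_de_int."
  ],
  "binding": {
    "hs7": {"coulomb": -311.7, "vdw": -37.5, "solvation": 255.9, "dg": -93.3},
    "hs1": {"coulomb": -327.1, "vdw": -51.3, "solvation": 274.3, "dg": -104.1},
    "hs3": {"coulomb": -307.3, "vdw": -48.6, "solvation": 255.9, "dg": -100.0},
    "hs4": {"coulomb": -319.5, "vdw": -49.4, "solvation": 263.1, "dg": -105.8},
    "hs5": {"coulomb": -313.7, "vdw": -40.4, "solvation": 258.0, "dg": -96.0},
    "hs6": {"coulomb": -315.0, "vdw": -40.5, "solvation": 260.4, "dg": -95.1},
    "nhk": {"coulomb": -323.2, "vdw": -49.4, "solvation": 269.1, "dg": -103.4},
    "z79": {"coulomb": -318.4, "vdw": -45.4, "solvation": 263.5, "dg": -100.3}
  },
  "fragments": {
    "hs7": {
      "ZBG": {"dq": 0.170, "de_net": 91.6, "dg_solv": 72.5, "half_de_int": -172.1},
      "NSO": {"dq": 0.052, "de_net": -6.3, "dg_solv": 22.5, "half_de_int": -44.3},
      "BZ":  {"dq": 0.086, "de_net": 23.5, "dg_solv": -9.6, "half_de_int": -21.2}
    },
    "hs1": {
      "ZBG": {"dq": 0.165, "de_net": 93.1, "dg_solv": 91.7, "half_de_int": -175.3},
      "NSO": {"dq": 0.081, "de_net": -6.0, "dg_solv": 4.7, "half_de_int": -51.8},
      "BZ":  {"dq": 0.077, "de_net": 24.6, "dg_solv": -10.4, "half_de_int": -26.8}
    },
    "hs3": {
      "ZBG": {"dq": 0.176, "de_net": 97.8, "dg_solv": 77.2, "half_de_int": -176.8},
      "NSO": {"dq": 0.054, "de_net": -2.2, "dg_solv": 14.1, "half_de_int": -49.0},
      "BZ":  {"dq": 0.070, "de_net": 30.8, "dg_solv": -5.0, "half_de_int": -31.1}
    },
    "hs4": {
      "ZBG": {"dq": 0.140, "de_net": 87.5, "dg_solv": 69.3, "half_de_int": -170.6},
      "NSO": {"dq": 0.052, "de_net": -8.8, "dg_solv": 21.9, "half_de_int": -42.6},
      "BZ":  {"dq": 0.129, "de_net": 14.5, "dg_solv": -12.5, "half_de_int": -23.5}
    },
    "hs5": {
      "ZBG": {"dq": 0.145, "de_net": 86.6, "dg_solv": 85.6, "half_de_int": -173.5},
      "NSO": {"dq": 0.073, "de_net": -6.6, "dg_solv": 9.7, "half_de_int": -47.1},
      "BZ":  {"dq": 0.130, "de_net": 15.2, "dg_solv": -12.5, "half_de_int": -24.3}
    },
    "hs6": {
      "ZBG": {"dq": 0.178, "de_net": 87.5, "dg_solv": 74.6, "half_de_int": -171.2},
      "NSO": {"dq": 0.053, "de_net": -4.1, "dg_solv": 20.7, "half_de_int": -44.2},
      "BZ":  {"dq": 0.068, "de_net": 29.5, "dg_solv": -8.8, "half_de_int": -28.5}
    },
    "nhk": {
      "ZBG": {"dq": 0.169, "de_net": 94.6, "dg_solv": 86.4, "half_de_int": -175.9},
      "NSO": {"dq": 0.074, "de_net": -6.0, "dg_solv": 6.6, "half_de_int": -46.4},
      "BZ":  {"dq": 0.075, "de_net": 26.7, "dg_solv": -10.8, "half_de_int": -30.5}
    },
    "z79": {
      "ZBG": {"dq": 0.173, "de_net": 91.2, "dg_solv": 78.8, "half_de_int": -175.8},
      "NSO": {"dq": 0.047, "de_net": -5.9, "dg_solv": 20.1, "half_de_int": -48.5},
      "BZ":  {"dq": 0.095, "de_net": 31.8, "dg_solv": -8.4, "half_de_int": -28.8}
    }
  },
  "metal_water_pair_terms": {
    "_comment": "selected metal-water interaction components in au for the hydrated Mg(II) system with six quantum waters: classical and exchange-correlation parts of the metal's interaction with the quantum waters",
    "Mg_Wat6": {"e_ele_qm": -0.5352, "e_xc_qm": -0.1394, "e_int_qm": -0.6746}
  }
}
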