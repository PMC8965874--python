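{
  "_comment": [
    "SYNTHETIC surrogate reference set for the pairwise D3(BJ) dispersion",
    "model.  The functional form implemented by iqakit.dispersion is the",
    "published third-generation (D3) scheme with Becke-Johnson rational",
    "damping; the original coordination-number-resolved reference-C6",
    "dataset is not redistributable from this environment, so this file",
    "ships a reduced surrogate: one reference point per element with",
    "homoatomic C6 coefficients taken from published free-atom dispersion",
    "coefficients (au), pair values by geometric-mean combination, r4r2",
    "factors from tabulated atomic <r4>/<r2> expectation-value ratios, and",
    "single-bond covalent radii (Angstrom).  Quantitative agreement with",
    "the original D3 parameterization is NOT claimed; see docs/methods.md."
  ],
  "k1": 16.0,
  "k2": 1.3333333333333333,
  "k3": 4.0,
  "damping": {
    "b3lyp": {"s6": 1.0, "s8": 1.9889, "a1": 0.3981, "a2": 4.4211},
    "hf": {"s6": 1.0, "s8": 0.9171, "a1": 0.3385, "a2": 2.883}
  },
  "elements": {
    "H":  {"c6_free": 6.5,   "r4r2": 8.0589,  "rcov": 0.32, "cn_ref": 0.91},
    "He": {"c6_free": 1.46,  "r4r2": 3.4698,  "rcov": 0.46, "cn_ref": 0.0},
    "C":  {"c6_free": 46.6,  "r4r2": 7.8715,  "rcov": 0.75, "cn_ref": 3.9},
    "N":  {"c6_free": 24.2,  "r4r2": 6.8103,  "rcov": 0.71, "cn_ref": 2.9},
    "O":  {"c6_free": 15.6,  "r4r2": 6.0556,  "rcov": 0.63, "cn_ref": 1.9},
    "F":  {"c6_free": 9.5,   "r4r2": 5.4231,  "rcov": 0.64, "cn_ref": 1.0},
    "P":  {"c6_free": 185.0, "r4r2": 10.1813, "rcov": 1.11, "cn_ref": 2.9},
    "S":  {"c6_free": 134.0, "r4r2": 9.3677,  "rcov": 1.03, "cn_ref": 1.9},
    "Cl": {"c6_free": 94.6,  "r4r2": 8.5584,  "rcov": 0.99, "cn_ref": 1.0},
    "Mg": {"c6_free": 627.0, "r4r2": 12.8884, "rcov": 1.39, "cn_ref": 0.0},
    "Zn": {"c6_free": 284.0, "r4r2": 10.8035, "rcov": 1.18, "cn_ref": 0.0}
  }
}
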