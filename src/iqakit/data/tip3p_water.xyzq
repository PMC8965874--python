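# element x y z q [eps rmin2 radius] (A, e, kcal/mol)
O  0.000000  0.000000  0.000000  -0.834  0.1520 1.7683 1.52
H  0.756950  0.000000  0.585882   0.417  0.0000 0.6000 1.20
H -0.756950  0.000000  0.585882   0.417  0.0000 0.6000 1.20
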