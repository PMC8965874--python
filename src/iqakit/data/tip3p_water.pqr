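ATOM      1  O   HOH     1       0.000   0.000   0.000 -0.834 1.52
ATOM      2  H1  HOH     1       0.757   0.000   0.586  0.417 1.20
ATOM      3  H2  HOH     1      -0.757   0.000   0.586  0.417 1.20
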