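# toy topology: two rigid waters (atoms 1-3, 4-6)
natoms 6
bond 1 2 450.0 0.9572
bond 1 3 450.0 0.9572
angle 2 1 3 55.0 104.52
bond 4 5 450.0 0.9572
bond 4 6 450.0 0.9572
angle 5 4 6 55.0 104.52
exclude 1 2
exclude 1 3
exclude 2 3
exclude 4 5
exclude 4 6
exclude 5 6
scee 1.2
scnb 2.0
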