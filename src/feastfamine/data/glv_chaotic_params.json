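{
 "r1": 1.0,
 "r2": -1.0,
 "A": [[0.0, -5.0], [17.0, 0.0]],
 "B0": 1.0,
 "T": 5.0
}
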