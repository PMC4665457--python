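{
 "design": "binary",
 "s": [[0, 9], [12, 14]],
 "r": [[0, 13], [9, 4]],
 "u": [[21, 0], [0, 0]]
}
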