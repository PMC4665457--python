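{
 "design": "binary",
 "s": [[3, 9], [12, 14]],
 "r": [[18, 13], [9, 4]],
 "u": [[10, 9], [8, 7]]
}
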