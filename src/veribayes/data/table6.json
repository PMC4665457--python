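{
 "design": "ordinal",
 "K": 3,
 "s": [8, 26, 51, 43, 81, 94, 117, 140, 208],
 "r": [101, 105, 83, 67, 72, 40, 41, 30, 4],
 "u": [2, 18, 62, 14, 83, 67, 63, 40, 108]
}
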