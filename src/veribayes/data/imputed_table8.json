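{
 "design": "ordinal",
 "K": 3,
 "s": [8, 30, 75, 48, 125, 141, 164, 173, 314],
 "r": [103, 119, 121, 76, 111, 60, 57, 37, 6],
 "u": [0, 0, 0, 0, 0, 0, 0, 0, 0]
}
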