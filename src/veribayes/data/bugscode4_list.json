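{
 "a_diseased": [8, 30, 75, 48, 0.125, 164, 141, 173, 314],
 "a_nondiseased": [103, 119, 121, 76, 111, 57, 60, 37, 6]
}
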