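pt,dose
16,10 m 30 s
17,10 m 30 s
20,4 m
21,15 m 45 s
24,11 m
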