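id,pvalue
1,0.01
2,0.5
3,0.08
4,0.18
5,0.18
6,0.7
7,0.9
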