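,1,2,3,4,5,6,7
1,0.0,0.5,3.0,3.4,3.8,10.0,10.5
2,0.5,0.0,2.5,2.9,3.3,9.5,10.0
3,3.0,2.5,0.0,0.3999999999999999,0.7999999999999998,7.0,7.5
4,3.4,2.9,0.3999999999999999,0.0,0.3999999999999999,6.6,7.1
5,3.8,3.3,0.7999999999999998,0.3999999999999999,0.0,6.2,6.7
6,10.0,9.5,7.0,6.6,6.2,0.0,0.5
7,10.5,10.0,7.5,7.1,6.7,0.5,0.0
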