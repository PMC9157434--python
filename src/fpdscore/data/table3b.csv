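hum_level,aut_0,aut_1,aut_2,aut_3,aut_4
0,30,10,2,0,0
1,44,200,24,5,2
2,48,431,1029,144,5
3,2,13,101,364,5
4,1,2,2,28,18
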