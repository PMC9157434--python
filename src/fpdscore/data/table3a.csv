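hum_level,aut_0,aut_1,aut_2,aut_3,aut_4
0,20,4,2,0,0
1,49,109,17,7,0
2,114,426,856,155,2
3,71,12,211,425,4
4,36,1,10,93,22
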