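e0,n0,e1,n1
7,107,12,105
17,118,18,120
30,252,49,263
25,109,19,109
35,167,35,168
17,137,26,140
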