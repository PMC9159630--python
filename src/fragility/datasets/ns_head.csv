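ma.id,e0,n0,e1,n1
1,3,24,4,20
1,2,10,1,9
1,2,28,0,22
1,31,265,46,260
1,6,32,4,28
1,4,35,5,39
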