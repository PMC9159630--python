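sid,tid,e,n
1,1,9,140
1,3,23,140
1,4,10,138
2,2,11,78
2,3,12,85
2,4,29,170
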