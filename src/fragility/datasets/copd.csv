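sid,tid,e,n
1,3,1,229
1,1,1,227
2,2,4,374
2,3,3,372
2,4,2,358
2,1,7,361
3,3,1,554
3,1,2,270
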