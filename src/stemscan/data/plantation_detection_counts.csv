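plot,n_trees,correct,false,omission,area_m2
1,16,16,0,0,100
2,14,13,0,1,100
3,22,19,0,3,100
4,17,16,0,1,100
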