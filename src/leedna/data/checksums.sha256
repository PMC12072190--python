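20bbf0e512e6e38322bb0366b49721faace872a5d3bf19fdafee2bc34ab10cb1  table1_bare.tsv
d1ae71a950c30b1d1d9beed6e071f68edff7ce8205d5b67081ef1cf9d10695d4  table1_argdna.tsv
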