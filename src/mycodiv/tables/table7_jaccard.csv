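site,site1,site2,site3,site4,site5,site6
site1,100,66,75,76,62,65
site2,66,100,69,57,70,75
site3,75,69,100,71,51,76
site4,76,57,71,100,63,62
site5,62,70,51,63,100,69
site6,65,75,76,62,69,100
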