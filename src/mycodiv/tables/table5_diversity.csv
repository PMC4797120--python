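label,factor,S,Np,G,GR,D,one_minus_D,H,E
summer,season,499,22,3.219,0.040,0.110,0.890,2.545,0.82
rainy,season,635,24,4.029,0.041,0.090,0.910,2.870,0.88
winter,season,762,17,2.411,0.021,0.121,0.879,2.310,0.81
site1,site,341,18,3.086,0.052,0.116,0.883,2.317,0.80
site2,site,320,22,3.640,0.065,0.117,0.883,2.358,0.83
site3,site,366,17,2.710,0.043,0.115,0.885,1.956,0.63
site4,site,277,19,3.378,0.068,0.128,0.872,2.365,0.80
site5,site,272,24,4.103,0.084,0.070,0.930,2.798,0.88
site6,site,318,20,3.123,0.056,0.104,0.896,2.506,0.83
stem,tissue,554,23,3.399,0.041,0.108,0.892,2.531,0.77
petiole,tissue,177,18,3.091,0.020,0.149,0.851,2.239,0.77
leaf,tissue,1165,24,3.640,0.090,0.096,0.904,2.618,0.80
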