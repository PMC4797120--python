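source,df,MS,F,p,significance
season,2,0.821,0.316,0.730,ns
site,5,2.717,1.046,0.395,ns
tissue,2,501.191,192.857,0.000,***
season x site x tissue,20,3.630,1.397,0.14,ns
season x site,10,8.614,3.314,0.001,***
season x tissue,4,8.404,3.234,0.015,**
site x tissue,10,4.006,1.542,0.135,ns
error,108,2.599,,,
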