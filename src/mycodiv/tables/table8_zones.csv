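extract,is_control,KP_mean,KP_sd,PA_mean,PA_sd,EC_mean,EC_sd
Coprinopsis cinerea,0,,,,,,
Penicillium spinulosum,0,,,,,,
Aspergillus flavus,0,11.0,0.76,,,,
Aspergillus sp.,0,,,12.15,0.28,,
Aspergillus peyronelii,0,,,,,,
Aspergillus niger,0,16.0,0.5,,,,
Aspergillus tubingensis,0,14.5,0.57,11.0,0.12,,
Chaetomium globosum,0,14.6,0.57,,,,
Aspergillus terreus,0,16.8,0.50,11.00,1.0,,
P. formosus,0,,,,,,
Control,1,22.0,0.50,20.0,0.50,18.0,0.57
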