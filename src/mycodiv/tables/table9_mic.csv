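extract,strain,mic_mg_ml
Aspergillus flavus,KP,2.50
Aspergillus niger,KP,0.62
Aspergillus tubingensis,KP,1.25
Chaetomium globosum,KP,1.25
Aspergillus terreus,KP,0.62
Aspergillus sp.,PA,2.50
Aspergillus tubingensis,PA,2.50
Aspergillus terreus,PA,2.50
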