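species,winter.1.leaf,winter.1.stem,winter.1.petiole,winter.2.leaf,winter.2.stem,winter.2.petiole,winter.3.leaf,winter.3.stem,winter.3.petiole,winter.4.leaf,winter.4.stem,winter.4.petiole,winter.5.leaf,winter.5.stem,winter.5.petiole,winter.6.leaf,winter.6.stem,winter.6.petiole
JP44MY2,1.4,0,0,0,0,0,0.74,0.74,0,2.2,2.2,0.74,6.6,0,0,3.7,2.9,0
JP44MY3,5.1,13.3,0,0,7.4,0,5.9,10.3,0.74,5.9,6.6,0.74,0,7.4,0,2.2,1.4,0
JP44MY4,0.74,0.74,0,0,0,0,0,0,0,7.4,1.4,1.4,2.9,1.4,0.74,0,0.74,0
JP44MY5,0.74,0,0,0,0,0,0,0,0,0,0,0,0.74,0,0.74,0,0,0
JP44MY6,2.9,0.74,2.2,2.2,0.74,0,7.4,1.4,0,11.1,1.4,1.4,1.4,0,0,2.9,0,0
JP44MY8,2.2,2.9,2.2,39.2,8.1,13.3,10.3,4.4,0.74,2.9,2.9,0.74,8.1,2.2,0.74,6.6,1.4,0.74
JP44MY9,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
JP44MY10,1.4,0,0,0,0,0,0,0,0,0,0,0,0.74,0,0,0,0,0
JP44MY12,2.2,0,2.2,5.1,1.4,2.2,2.9,0.74,0,0,0,0,0,0,0,0,0,0
JP44MY13,1.4,0,0,0.74,0,0,0,0,0,2.9,0,0,0.74,0,0,0,2.9,0
JP44MY14,8.8,2.2,2.2,0,0.74,0,1.4,0,13.3,3.7,0.74,0,24.4,0.74,0,6.6,4.4,0.74
JP44MY16,15.5,20,5.9,45.9,29.6,5.9,59.2,14.8,0,0,1.4,0.74,8.8,4.4,1.4,9.6,0,0.74
JP44MY18,3.7,0,0,0,0,0,0,0,0,12.5,1.4,0,4.4,0.74,0,0,0,2.2
JP44MY22,0,0,0,0,0,0,0,0,0,1.4,0.74,10.3,0,0,0,0,0,0
JP44MY23,5.9,2.9,0,5.1,0,0,7.4,2.2,0,49.6,13.3,0,21.4,5.1,1.4,40.7,14.0,2.9
JP44MY24,4.4,4.4,0,1.4,0,0,1.4,2.9,0,0,2.9,0,1.4,0,0.74,0,0.74,0
JP44MY25,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
JP44MY26,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
JP44MY27,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
JP44MY28,0,0,0,0,0,0,0,0,0,0,0,0,1.4,1.4,0.74,0,0,0
JP44MY35,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
JP44MY41,2.2,4.4,6.6,0,0,1.4,8.8,4.4,0,0,0,0,0,0,0,2.9,0.74,0
JP44MY42,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
JP44MY43,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
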