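species,rainy.1.leaf,rainy.1.stem,rainy.1.petiole,rainy.2.leaf,rainy.2.stem,rainy.2.petiole,rainy.3.leaf,rainy.3.stem,rainy.3.petiole,rainy.4.leaf,rainy.4.stem,rainy.4.petiole,rainy.5.leaf,rainy.5.stem,rainy.5.petiole,rainy.6.leaf,rainy.6.stem,rainy.6.petiole
JP44MY2,1.4,0,0,0,0,0,0.74,0,0.74,0,0.74,0,3.7,0,1.4,3.7,0,0
JP44MY3,0,7.4,0,3.7,8.1,1.4,2.2,5.9,0,0,0,0,2.2,2.9,0.74,0,11.1,2.2
JP44MY4,0,0,0,2.2,0.74,0,0.74,2.2,0,0,0,0,1.4,0,0,1.4,1.4,0
JP44MY5,0.74,0,0,1.2,0,0,2.2,0,0,0,0,0,1.4,9.6,0.74,0,0,0
JP44MY6,0.74,2.2,0,2.2,0.74,0.74,1.4,0,0,0.74,0,0.74,1.4,0,0,3.7,5.1,0
JP44MY8,0,0,1.4,1.4,0,0,2.2,0.74,0,0,0,0.74,3.7,0,0,1.4,1.4,0
JP44MY9,1.4,0,0,0,0,0,0.74,0,0,0,0,0,0.74,0,0,0,0,0
JP44MY10,1.4,1.4,0,0,0,0.74,0.74,0,0,0,0,0,1.4,0,0,0,0,0
JP44MY12,2.2,2.9,0,3.7,1.4,1.4,2.2,2.2,0,0,0,0,1.4,1.4,0,1.4,0.74,0
JP44MY13,0,0,1.4,1.4,0,0,2.9,0,0,1.4,0.74,0,1.4,0,0,0,0,0
JP44MY14,9.6,4.4,2.2,5.1,1.4,0,28.8,0.74,0,8.1,0,0,0,0,0,6.6,2.2,0.74
JP44MY16,2.2,4.4,3.7,3.7,1.4,0.74,8.8,12.5,7.4,11.1,0,0.74,0.74,0.74,0.74,7.4,0,0
JP44MY18,3.7,3.7,1.4,4.4,1.4,1.4,2.2,1.4,2.2,3.7,2.2,2.2,7.4,1.4,0,5.9,1.4,0
JP44MY22,1.4,0,0,0.74,2.2,0,0,0,0,14.8,0,3.7,3.7,1.4,0,2.5,3.7,2.2
JP44MY23,5.1,0,0.74,10.3,3.7,3.7,0,0,0,9.6,0.74,0.74,1.4,0,0.74,0.74,2.2,0
JP44MY24,0,0.74,0,2.2,0,0,0,0,0,0.74,0,0,0,0,0,0,0,0
JP44MY25,0,0,0,1.4,0,0,0,0,0,1.4,2.9,0,0,0,2.2,1.4,2.2,0
JP44MY26,0,0,0,0,0,0,0,0,0,0,0,0.74,0,0,0,0,0,0
JP44MY27,1.4,0.74,1.4,0.74,0,0.74,0,0,0,0,0.74,0,0,0,0,0,0,0
JP44MY28,0,0,0,0,0,0,0,0,0,0,0.74,0,1.4,2.9,0,0,0,0
JP44MY35,0.74,0,0,0,1.4,0,0,0,0,0,0,0,0.74,0,0,0,0.74,0
JP44MY41,0,0,0,0.74,0,0,0,0,0,0,2.9,0,2.2,0,0,0,0,0
JP44MY42,2.9,0,0.74,0,0,0,0,0,0,0,0,0,1.4,0,0,0,0,0
JP44MY43,0,0,0,0.74,0,0,0,0,0,0,0,0,0,0,0,1.4,0,0
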