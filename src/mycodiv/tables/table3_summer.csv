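species,summer.1.leaf,summer.1.stem,summer.1.petiole,summer.2.leaf,summer.2.stem,summer.2.petiole,summer.3.leaf,summer.3.stem,summer.3.petiole,summer.4.leaf,summer.4.stem,summer.4.petiole,summer.5.leaf,summer.5.stem,summer.5.petiole,summer.6.leaf,summer.6.stem,summer.6.petiole
JP44MY2,0,0,0,0,0,0,0,0,0,0,0,0,0.74,0,0,0,0,0
JP44MY3,0,0.74,0,0,2.2,0,0,5.1,0,0,0.74,0,0,4.4,0,0,0.74,0
JP44MY4,7.4,0,0,0,0,0,2.2,0,0,0,0,0,0,0,0,0,0,0
JP44MY5,0,0,0,0,0.74,0,0,0,0,0.74,0,0,0,0,0,0,0,0
JP44MY6,1.4,0,0.74,2.2,0,0,2.9,1.4,0,1.4,0.74,0,0.74,0.74,0,0.74,1.4,0
JP44MY8,2.2,0,0.74,0.74,1.4,0,1.4,0.74,0,2.2,0.74,0,0,0,0,2.2,0,0
JP44MY9,0,0,0,0.74,0.74,0,0,0,0,0,0,0,0,0,0,0,0,0
JP44MY10,0.74,0.74,0,0.74,0,0,2.2,1.4,0,2.2,0.74,0,0,0,0,1.4,0.74,0
JP44MY12,0,3.7,0,2.2,0,0,4.4,2.2,0.74,0,1.4,0,0.74,0,0,0.74,0,0
JP44MY13,0,0,0.74,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
JP44MY14,4.4,2.2,0,5.1,3.7,0,11.8,4.4,0,0,0.74,0.74,0.74,0.74,0,1.4,0,0
JP44MY16,5.1,0,0,10.3,1.4,0.74,8.1,2.2,0,0,6.6,0.74,7.4,1.4,2.2,12.5,0,2.2
JP44MY18,2.9,0.74,0,3.7,0.74,0,1.4,1.4,0,2.2,0.74,0,1.4,0,0,8.8,1.4,1.4
JP44MY22,1.4,0.74,0.74,0.74,2.9,1.4,2.9,2.2,0,11.8,2.9,0.74,0,0,0,0.74,0,0
JP44MY23,18.5,5.1,8.1,13.3,2.9,0,46.6,21.4,8.1,5.9,0,0,1.4,0,0,3.7,1.4,0.74
JP44MY24,0,0,0,1.4,0,0,0,0,0,0,0,0,0,0.74,0,0,0,0
JP44MY25,0,0,0,1.4,0,0,1.4,0,0,2.2,0,0,0,0,0,0,0,0
JP44MY26,0.74,0,0,0,0,0,0,0,0,0,0,0,0.74,0,0,0,0,0
JP44MY27,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
JP44MY28,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
JP44MY35,0.74,0,0.74,0,0.74,0,0,0,0,0,0,0,0,0.74,0,0,0,0
JP44MY41,1.4,0,0,0,0,0,0.74,0,0,0,0,0,2.2,0,0,0,0,0
JP44MY42,1.4,0,0,0.74,0,0,0,0,0,2.2,0,0,0,0,0,0.74,0,0
JP44MY43,0,0,0,0,0,0,0,0,0,0,0,0,0.74,0,0,0,0,0
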