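species,family,origin,is_target
Agrotis subterranea,Noctuidae,uncertain,False
Helicoverpa zea,Noctuidae,uncertain,False
Monodes spp.,Noctuidae,uncertain,False
Pseudaletia unipuncta,Noctuidae,uncertain,False
Spodoptera spp.,Noctuidae,uncertain,False
Spodoptera praefica,Noctuidae,uncertain,False
Spodoptera frugiperda,Noctuidae,uncertain,False
Spodoptera exigua,Noctuidae,uncertain,False
Colias eurytheme,Pieridae,uncertain,False
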