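species,family,origin,is_target
Pseudaletia latiuscula,Noctuidae,uncertain,False
Spoladea recurvalis,Crambidae,uncertain,False
Spodoptera exigua,Noctuidae,uncertain,False
Spodoptera frugiperda,Noctuidae,uncertain,False
Spodoptera praefica,Noctuidae,uncertain,False
Udea rubigalis,Crambidae,uncertain,False
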