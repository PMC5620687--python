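species,family,origin,is_target
Agrotis hephaestaea,Noctuidae,endemic,False
Ethmia nigroapicella,Oecophoridae,adventive,False
Eudonia sp.,Crambidae,endemic,False
Eupithecia monticolens,Geometridae,endemic,False
Fletcherana leucoxyla,Geometridae,endemic,False
Haliophyle euclidias,Noctuidae,endemic,False
Scotorythra arboricolans,Geometridae,endemic,False
Scotorytorythra caryopis,Geometridae,endemic,False
Scotorythra hecataea,Geometridae,endemic,False
Scotorythra pauludicola,Geometridae,endemic,False
Scotorythra rara,Geometridae,endemic,False
Scotorythra trapezias,Geometridae,endemic,False
Scotorythra spp.,Geometridae,endemic,False
Spodalea recurvalis,Crambidae,adventive,False
Pseudaletia unipuncta,Noctuidae,adventive,False
Spodoptera exempta,Noctuidae,adventive,True
Spodoptera mauritia,Noctuidae,adventive,False
Spheretista pleonectes,Tortricidae,endemic,False
Udea stellata,Crambidae,endemic,False
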