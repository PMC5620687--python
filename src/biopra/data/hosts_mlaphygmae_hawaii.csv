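species,family,origin,is_target
Agraulis vanillae,Nymphalidae,adventive,False
Agrotis hephaestaea,Noctuidae,endemic,False
Agrotis ipsilon,Noctuidae,adventive,True
Amorbia emigratella,Tortricidae,adventive,False
Amyna natalis,Noctuidae,adventive,False
Autegumia ebulealis,Crambidae,introduced,False
Elaphria nucicolora,Noctuidae,adventive,False
Eudonia sp.,Crambidae,endemic,False
Eupithecia monticolens,Geometridae,endemic,False
Fletcherana leucoxyla,Geometridae,endemic,False
Haliophyle euclidias,Noctuidae,endemic,False
Helicoverpa zea,Noctuidae,adventive,False
Herpetogramma licarsisalis,Crambidae,adventive,False
Melipotis indomita,Noctuidae,adventive,False
Omiodes accepta,Crambidae,endemic,False
Rynchopalpus brunellus,Noctuidae,introduced,False
Scotorythra spp.,Geometridae,endemic,False
Scotorythra apicalis,Geometridae,endemic,False
Scotorythra hecataea,Geometridae,endemic,False
Scotorythra ortharcha,Geometridae,endemic,False
Scotorythra rara,Geometridae,endemic,False
Scotorythra paludicola,Geometridae,endemic,False
Scotorythra trapezias,Geometridae,endemic,False
Spodoptera exempta,Noctuidae,adventive,True
Spodoptera exigua,Noctuidae,adventive,True
Spodoptera mauritia,Noctuidae,adventive,True
Thyracopa spp.,Oecophoridae,endemic,False
Udea stellata,Crambidae,endemic,False
Udea pyranthes,Crambidae,endemic,False
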