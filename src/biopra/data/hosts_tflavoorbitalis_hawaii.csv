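species,family,origin,is_target
Agonoxena argaula,Agonoxenidae,adventive,False
Asymphorodes dimorpha,Asymphorodes,adventive,False
Bradleyella metallurgica,Tortricidae,endemic,False
Bracta straminea,Tortricidae,uncertain,False
Bracta venosana,Tortricidae,introduced,False
Carposina gramicolor,Carposinidae,endemic,False
Chedra microstigma,Batrachedridae,adventive,False
Chilo supressalis,Crambidae,adventive,False
Crocidosema blackburni,Tortricidae,uncertain,False
Crocidosema marcidella,Tortricidae,uncertain,False
Crocidosema lantana,Tortricidae,introduced,False
Cryptophlebia illepida,Tortricidae,adventive,False
Erechthias minuscula,Tineidae,adventive,False
Herpetogramma licarsisalis,Crambidae,adventive,False
Omiodes accepta,Crambidae,endemic,False
Omiodes blackburni,Crambidae,endemic,False
Omiodes localis,Crambidae,endemic,False
Omiodes meyricki,Crambidae,endemic,False
Omiodes monogramma,Crambidae,endemic,False
Omiodes muniscola,Crambidae,endemic,False
Pyroderces rileyi,Cosmopterigidae,adventive,False
Spheterista infaustana,Tortricidae,endemic,False
Spheterista reynoldsiana,Tortricidae,endemic,False
Spodalea recurvalis,Crambidae,adventive,False
Thyrocopa spp.,Oecophoridae,endemic,False
Udea chalcophanes,Crambidae,endemic,False
Udea micacea,Crambidae,endemic,False
Udea platyleuca,Crambidae,endemic,False
Udea stellata,Crambidae,endemic,False
Udea violae,Crambidae,endemic,False
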