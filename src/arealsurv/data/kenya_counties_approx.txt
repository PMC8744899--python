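# Approximate first-order contiguity for the 47 Kenyan counties.
# Hand-assembled from a small-scale administrative map (rook-style);
# NOT shapefile-derived. Each undirected edge listed once.
Mombasa Kwale
Mombasa Kilifi
Kwale Kilifi
Kwale TaitaTaveta
Kilifi TanaRiver
Kilifi TaitaTaveta
TanaRiver Lamu
TanaRiver Garissa
TanaRiver Kitui
TanaRiver TaitaTaveta
TanaRiver Isiolo
Lamu Garissa
TaitaTaveta Makueni
TaitaTaveta Kajiado
Garissa Wajir
Garissa Isiolo
Garissa Kitui
Wajir Mandera
Wajir Marsabit
Wajir Isiolo
Marsabit Turkana
Marsabit Samburu
Marsabit Isiolo
Isiolo Samburu
Isiolo Laikipia
Isiolo Meru
Isiolo TharakaNithi
Meru TharakaNithi
Meru Laikipia
Meru Nyeri
TharakaNithi Embu
TharakaNithi Kitui
Embu Kitui
Embu Machakos
Embu Kirinyaga
Kitui Machakos
Kitui Makueni
Machakos Makueni
Machakos Kajiado
Machakos Nairobi
Machakos Kiambu
Machakos Muranga
Makueni Kajiado
Nairobi Kiambu
Nairobi Kajiado
Kiambu Muranga
Kiambu Nyandarua
Kiambu Nakuru
Kiambu Kajiado
Muranga Kirinyaga
Muranga Nyeri
Muranga Nyandarua
Kirinyaga Nyeri
Nyeri Nyandarua
Nyeri Laikipia
Nyandarua Laikipia
Nyandarua Nakuru
Laikipia Nakuru
Laikipia Baringo
Laikipia Samburu
Turkana WestPokot
Turkana Baringo
Turkana Samburu
WestPokot TransNzoia
WestPokot ElgeyoMarakwet
WestPokot Baringo
Samburu Baringo
TransNzoia Bungoma
TransNzoia UasinGishu
TransNzoia ElgeyoMarakwet
TransNzoia Kakamega
UasinGishu ElgeyoMarakwet
UasinGishu Nandi
UasinGishu Kericho
UasinGishu Baringo
UasinGishu Kakamega
ElgeyoMarakwet Baringo
Nandi Kakamega
Nandi Vihiga
Nandi Kisumu
Nandi Kericho
Baringo Nakuru
Nakuru Kericho
Nakuru Bomet
Nakuru Narok
Kericho Bomet
Kericho Kisumu
Bomet Narok
Bomet Nyamira
Narok Kajiado
Narok Nyamira
Narok Migori
Bungoma Busia
Bungoma Kakamega
Busia Kakamega
Busia Siaya
Kakamega Vihiga
Vihiga Siaya
Vihiga Kisumu
Siaya Kisumu
Kisumu HomaBay
Kisumu Nyamira
HomaBay Migori
HomaBay Kisii
Migori Kisii
Kisii Nyamira
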