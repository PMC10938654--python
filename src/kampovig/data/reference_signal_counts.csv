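section,label,group,total_n,case_n,noncase_n,ror,ci_low,ci_high
group,SR,SR,1051,308,743,9.0,7.9,10.3
product,Bofutsushosan,SR,410,103,307,7.3,5.8,9.1
product,Orengedokuto,SR,185,44,141,6.7,4.8,9.5
product,Shin'iseihaito,SR,110,27,83,7.0,4.6,10.8
product,Seishinrenshiin,SR,99,51,48,23.0,15.5,34.1
product,Junchoto,SR,46,25,21,25.7,14.4,45.9
product,Unseiin,SR,42,13,29,9.7,5.0,18.6
product,Seihaito,SR,34,11,23,10.3,5.0,21.2
product,Seijobofuto,SR,28,1,27,,,
product,Ryutanshakanto,SR,24,9,15,13.0,5.7,29.6
product,Sammotsuogonto,SR,23,11,12,19.8,8.7,44.9
product,Nyoshinsan,SR,22,3,19,3.4,1.0,11.5
product,Gorinsan,SR,21,6,15,8.6,3.3,22.3
product,San'oshashinto,SR,6,4,2,43.2,7.9,235.7
product,Ogonto,SR,1,0,1,,,
group,BR,BR,796,86,710,2.6,2.1,3.3
product,Yokukansan,BR,418,42,376,2.4,1.8,3.3
product,Hochuekkito,BR,181,32,149,4.6,3.2,6.8
product,Kamishoyosan,BR,153,7,146,1.0,0.5,2.2
product,Kamikihito,BR,21,3,18,3.6,1.1,12.2
product,Jumihaidokuto,BR,19,2,17,2.5,0.6,11.0
product,Shimpito,BR,2,0,2,,,
product,Shigyakusan,BR,1,0,1,,,
product,Jiinshihoto,BR,1,0,1,,,
group,PT,PT,482,77,405,4.1,3.2,5.2
product,Rikkunshito,PT,158,13,145,1.9,1.1,3.4
product,Bakumondoto,PT,131,31,100,6.7,4.5,10.0
product,Shoseiryuto,PT,110,20,90,4.8,3.0,7.8
product,Hangekobokuto,PT,45,10,35,6.2,3.1,12.5
product,Chotosan,PT,14,1,13,,,
product,Hangebyakujutsutemmato,PT,7,1,6,,,
product,Unkeito,PT,6,0,6,,,
product,Bukuryoingohangekobokuto,PT,5,0,5,,,
product,Goshakusan,PT,3,0,3,,,
product,Shohangekabukuryoto,PT,1,0,1,,,
product,Nichinto,PT,1,0,1,,,
product,Ryokankyomishingeninto,PT,1,1,0,,,
product,Orento,PT,0,0,0,,,
product,Jinsoin,PT,0,0,0,,,
product,Tokito,PT,0,0,0,,,
group,SR_BR,SR_BR,277,115,162,15.4,12.1,19.5
product,Otsujito,SR_BR,154,82,72,24.6,17.9,33.8
product,Saikokeishikankyoto,SR_BR,78,23,55,9.0,5.5,14.7
product,Keigairengyoto,SR_BR,41,8,33,5.2,2.4,11.3
product,Saikoseikanto,SR_BR,4,2,2,21.6,3.0,153.1
group,SR_PT,SR_PT,231,102,129,17.1,13.2,22.2
product,Hangeshashinto,SR_PT,190,81,109,16.1,12.0,21.4
product,Nijutsuto,SR_PT,41,21,20,22.7,12.3,41.8
group,BR_PT,BR_PT,31,3,28,2.3,0.7,7.6
product,Yokukansankachimpihange,BR_PT,28,2,26,1.7,0.4,7.0
product,Chikujountanto,BR_PT,3,1,2,,,
group,SR_BR_PT,SR_BR_PT,998,383,615,13.6,11.9,15.4
product,Saireito,SR_BR_PT,456,191,265,15.6,13.0,18.8
product,Saikokaryukotsuboreito,SR_BR_PT,164,50,114,9.5,6.8,13.2
product,Shosaikoto,SR_BR_PT,107,58,49,25.6,17.5,37.4
product,Saibokuto,SR_BR_PT,93,29,64,9.8,6.3,15.2
product,Saikokeishito,SR_BR_PT,85,23,62,8.0,5.0,12.9
product,Daisaikoto,SR_BR_PT,64,25,39,13.8,8.4,22.9
product,Shosaikokakikyosekko,SR_BR_PT,25,7,18,8.4,3.5,20.1
product,Daisaikotokyodaio,SR_BR_PT,4,0,4,,,
product,Saikanto,SR_BR_PT,0,0,0,,,
sex,Male,,2560,808,1752,10.2,9.3,11.0
sex,Female,,4285,719,3566,4.4,4.1,4.8
age,<20,,172,6,166,0.8,0.3,1.8
age,20s,,200,7,193,0.8,0.4,1.7
age,30s,,477,16,461,0.7,0.5,1.2
age,40s,,617,50,567,1.9,1.4,2.5
age,50s,,892,153,739,4.5,3.8,5.3
age,60s,,1276,385,891,9.4,8.4,10.6
age,70s,,1657,534,1123,10.4,9.4,11.5
age,80s+,,1450,354,1096,7.0,6.2,7.9
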