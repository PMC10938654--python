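product_name,full_daily_dose_g,SR,BR,PT,jujube,ginseng,glycyrrhiza,ginger
Bofutsushosan,7.5,2.0,,,,,2.0,0.3
Orengedokuto,7.5,3.0,,,,,,
Seishinrenshiin,7.5,3.0,,,,3.0,2.0,
Yokukansan,7.5,,2.0,,,,1.5,
Hochuekkito,7.5,,2.0,,2.0,4.0,1.5,0.5
Kamishoyosan,7.5,,3.0,,,,1.5,1.0
Rikkunshito,7.5,,,4.0,2.0,4.0,1.0,0.5
Bakumondoto,9.0,,,5.0,3.0,2.0,2.0,
Shoseiryuto,9.0,,,6.0,,,3.0,
Otsujito,7.5,3.0,5.0,,,,2.0,
Saikokeishikankyoto,7.5,3.0,6.0,,,,2.0,1.0
Hangeshashinto,7.5,2.5,,5.0,2.5,2.5,2.5,
Shosaikoto,7.5,3.0,7.0,5.0,3.0,3.0,2.0,1.0
Saireito,9.0,3.0,7.0,5.0,3.0,3.0,2.0,1.0
Saikokaryukotsuboreito,7.5,2.5,5.0,4.0,2.5,2.5,,
Saibokuto,7.5,3.0,7.0,5.0,3.0,3.0,2.0,1.0
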