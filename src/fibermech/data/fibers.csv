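name,type,totcel_min,totcel_avg,totcel_max,hemcel_min,hemcel_avg,hemcel_max,lig_min,lig_avg,lig_max,pec_min,pec_avg,pec_max,ash_min,ash_avg,ash_max,npor_min,npor_avg,npor_max,xi_min,xi_avg,xi_max,mfa_min,mfa_avg,mfa_max,rho_min,rho_avg,rho_max,assumed
Banana,bast,60,71,82,6,10,14,5,8,10,0,4,4,0,5,5,0,0,0,30,45,49,11,11,12,1.3,1.4,1.5,
Flax,bast,71,73,81,15,18,21,2,3,3,,1,,,0,,,2,,50,78,90,5,6,10,1.38,1.38,1.5,
Hemp,bast,57,70,81,18,20,22,4,5,6,,1,,,0,,,1,,50,75,98,6,7,10,1.35,1.4,1.5,
Isora,bast,71,71,75,0,3,3,14,21,23,,0,,0,0,1,,0,,34,71,71,20,23,26,1.2,1.3,1.3,
Jute,bast,45,58,72,12,18,23,9,18,26,0,0,0,,0,,,0,,68,71,73,7,8,9,1.23,1.35,1.5,
Kenaf,bast,31,56,81,,22,,15,17,19,,2,,,0,,,0,,61,65,69,9,12,15,1.2,1.22,1.4,
Ramie,bast,69,80,91,5,14,17,1,1,1,,2,,,0,,,0,,,64,,6,8,10,1.44,1.44,1.55,
Sorghum,bast,,65,,,19,,,10,,,0,,,5,,,0,,32,43,53,16,16,17,,0.89,,
Alfa,grass,,45,,,39,,,39,,,0,,,0,,,2,,,64,,,10,,,0.89,,mfa
Bagasse,grass,32,37,48,19,23,28,23,7,32,0,10,10,2,4,5,0,2,4,,48,,14,15,15,0.55,1.2,1.25,
Bamboo,grass,35,35,47,15,21,23,21,26,31,0,0,0,,0,,,0,,40,56,60,2,6,10,1.2,1.3,1.5,
Abaca,leaf,56,63,70,14,20,25,7,9,12,0,1,1,0,2,2,3,6,6,,52,,,23,,,1.5,,
Curaua,leaf,,74,,,10,,,8,,,0,,,0,,,1,,,66,,15,17,19,,1.4,,
Henequen,leaf,60,64,68,18,23,28,8,8,9,,0,,0,1,1,,5,,44,47,50,18,20,22,1.33,1.4,1.4,
Phormium,leaf,,67,,,30,,,11,,,0,,,0,,,0,,,69,,,10,,,1.27,,mfa
Pineapple,leaf,70,75,85,,18,,5,8,12,0,4,4,1,1,1,,0,,44,52,60,6,12,14,1.32,1.5,1.56,
Sisal,leaf,38,63,88,10,14,26,8,12,25,0,10,10,,0,,,3,,68,73,77,10,20,25,1.2,1.35,1.5,
Coir,fruit/seed,21,40,46,12,20,31,20,35,47,0,4,4,0,10,10,0,0,9,27,30,33,30,45,49,1.2,1.2,1.25,
Kapok,fruit/seed,53,59,64,29,30,30,13,17,22,,0,,1,1,1,,4,,,46,,,10,,,0.38,,mfa
Oil Palm,fruit/seed,43,54,65,17,25,34,13,19,25,0,0,0,1,4,6,,7,,20,25,30,,46,,0.7,1.35,1.55,
Barley,straw,31,38,45,27,33,38,14,17,19,,0,,,0,,,0,,,50,,,10,,,0.52,,mfa;xi;rho
Cornhusk,straw,47,54,61,20,32,44,2,3,4,,0,,3,8,13,,0,,48,74,100,,10,,0.43,0.52,0.61,mfa
Cornstalk,straw,38,39,40,,28,,7,14,21,,0,,4,0,7,,0,,52,76,100,,11,,,0.52,,rho
Rice,straw,28,32,36,23,26,28,12,13,14,,0,,14,17,20,,0,,40,60,63,,10,,,1.65,,mfa
Soybean,straw,35,85,88,0,5,17,5,11,22,,0,,1,2,11,,0,,43,47,51,,12,,,0.52,,rho
Wheat,straw,33,36,38,26,29,32,17,18,19,,0,,2,0,7,,0,,48,51,51,,0,,1.45,1.53,1.6,
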