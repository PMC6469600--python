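site_id,altitude_m,ph_cacl2,clay_pct,silt_pct,apparent_density_g_cm3,soc_g_per_kg,stock_t_ha,manure_liquid,manure_liquid_1985_1999,manure_liquid_2000_2014,manure_solid,manure_solid_1985_1999,manure_solid_2000_2014,prop_meadow,prop_meadow_1985_1999,prop_meadow_2000_2014,prop_cereal,prop_cereal_1985_1999,prop_cereal_2000_2014,prop_hoe,prop_hoe_1985_1999,prop_hoe_2000_2014,status
1,684,5.2,16,38,1.21,11.9,29,0,0,0,0,0,0,0,0,0,61,67,56,39,33,44,cropland
2,557,6.0,12,35,1.30,12.0,31,640,790,500,590,360,810,0,0,0,32,33,31,61,67,56,cropland
3,324,5.3,15,72,1.46,12.8,38,950,530,1370,470,750,190,9,10,7,21,40,0,12,23,0,cropland
4,428,5.3,17,25,0.83,13.2,22,,,,,,,,,,,,,,,,cropland
5,488,6.4,15,16,1.38,14.4,40,900,1130,670,250,490,0,60,40,80,20,33,7,20,27,13,converted_to_grassland
6,482,5.7,16,67,1.24,13.7,34,220,200,240,1010,1120,890,0,0,0,71,73,70,29,27,30,cropland
7,379,7.2,6,60,1.14,14.8,34,0,0,0,90,0,180,0,0,0,41,42,40,59,58,60,cropland
8,343,5.8,15,46,1.33,15.2,40,,,,,,,,,,,,,,,,cropland
9,336,5.9,21,38,1.19,15.5,37,70,0,140,2550,2280,2810,22,25,20,26,33,20,52,42,60,cropland
10,417,5.3,14,33,1.04,16.5,34,1010,2020,0,550,820,280,22,46,0,15,8,21,63,46,79,cropland
11,435,6.1,19,45,1.27,17.5,45,0,0,0,520,690,350,0,0,0,55,58,53,45,42,47,cropland
12,455,5.3,17,23,1.07,17.2,37,1780,0,3560,800,860,740,37,0,47,37,50,33,26,50,20,cropland
13,559,6.2,24,44,1.21,17.8,43,990,980,1000,2990,2460,3510,41,42,40,39,46,33,20,12,27,cropland
14,465,5.2,14,34,1.09,19.1,42,330,500,160,1510,1940,1090,18,42,0,43,25,56,39,33,44,cropland
15,538,5.4,26,67,1.18,18.8,44,340,100,570,1170,1560,780,0,0,0,59,67,53,41,33,47,cropland
16,440,7.2,10,23,1.01,19.9,40,,,,,,,,,,,,,,,,cropland
17,478,5.9,28,23,1.26,20.7,52,1620,1750,1490,810,830,790,48,36,60,24,29,20,28,36,20,cropland
18,618,5.1,18,38,1.13,21.6,49,1740,1410,2070,0,0,0,52,58,47,30,25,33,19,17,20,cropland
19,945,5.1,14,20,1.02,21.5,44,2130,1840,2430,5690,9480,1910,57,54,60,24,29,20,19,18,20,cropland
20,515,6.5,24,24,1.07,21.7,46,760,690,830,590,1180,0,43,21,62,40,43,38,17,36,0,cropland
21,450,5.4,36,45,1.23,23.7,58,,,,,,,,,,,,,,,,cropland
22,770,5.9,21,18,1.08,23.1,50,720,820,630,970,840,1110,26,27,25,48,47,50,26,27,25,cropland
23,500,5.8,26,36,1.07,23.6,51,2030,1330,2730,1570,1600,1550,66,36,93,14,29,0,17,29,7,converted_to_grassland
24,450,5.6,31,31,1.11,27.1,60,2000,2620,1380,100,0,190,39,50,29,25,14,36,36,36,36,cropland
25,830,6.8,18,51,1.13,28.3,64,660,580,750,3630,2200,5060,48,42,53,30,33,27,22,25,20,cropland
26,545,7.2,59,30,0.97,28.9,56,1510,1730,1300,1240,1610,870,13,0,25,30,43,19,47,57,38,cropland
27,439,7.5,43,46,1.06,29.7,63,390,670,120,1190,380,1990,7,0,12,36,42,31,57,58,56,cropland
28,534,7.3,22,38,0.95,33.7,64,,,,,,,,,,,,,,,,cropland
29,626,7.1,41,46,0.78,36.8,58,,,,,,,,,,,,,,,,cropland
30,532,7.2,37,47,1.05,38.2,80,910,640,1170,1520,1780,1270,25,25,25,32,33,31,43,42,44,cropland
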