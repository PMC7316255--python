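variety_code,name,group,n_total,n_unmethylated,pct_unmethylated,n_cg,pct_cg,n_chg,pct_chg,n_total_methylated,pct_total_methylated
M1,Fuji,Origin,1841,1212,65.834,396,21.51,233,12.656,629,34.166
M2,Shanfu No.6,Color,2112,1227,58.097,402,19.034,483,22.869,885,41.903
M3,Iwate line I,Color,1880,1134,60.319,475,25.266,271,14.415,746,39.681
M4,Iwafu No.10,Color,1904,1163,61.082,478,25.105,263,13.813,741,38.918
M5,Line I Fuji,Color,1996,1136,56.914,552,27.655,308,15.431,860,43.086
M6,Gunfu No.1,Color,1875,1268,67.627,363,19.36,244,13.013,607,32.373
M7,Aki Fuji,Color,1893,1231,65.029,453,23.93,209,11.041,662,34.971
M8,Lele Fuji,Color,1962,1222,62.283,497,25.331,243,12.385,740,37.717
M9,Aomori-fu No.13,Color,2025,1263,62.37,363,17.926,399,19.704,762,37.63
M10,2001,Color,1874,1231,65.688,396,21.131,247,13.18,643,34.312
M11,Aki-fu No.1,Color,1872,1238,66.132,438,23.397,196,10.47,634,33.868
M12,Aki-fu No.5,Color,1910,1270,66.492,433,22.67,207,10.838,640,33.508
M13,Morioka-fu No.1,Color,2018,1294,64.123,363,17.988,361,17.889,724,35.877
M14,Morioka-fu No.2,Color,1950,1289,66.103,373,19.128,288,14.769,661,33.897
M15,Tensei,Color,1989,1260,63.348,471,23.68,258,12.971,729,36.652
M16,Qingnonghe No.2,Color,1916,1288,67.223,387,20.198,241,12.578,628,32.777
M17,Qianxuan No.3,Color,1908,1263,66.195,380,19.916,265,13.889,645,33.805
M18,Fubrax,Color,1871,1231,65.794,411,21.967,229,12.239,640,34.206
M19,Nagafu No.12,Color,1939,1287,66.374,353,18.205,299,15.42,652,33.626
M20,Nagafu No.1,Color,1923,1266,65.835,341,17.733,316,16.433,657,34.165
M21,Nagafu No.2,Color,1998,1281,64.114,406,20.32,311,15.566,717,35.886
M22,Nagafu No.4,Color,1928,1272,65.975,399,20.695,257,13.33,656,34.025
M23,Nagafu No.6,Color,2026,1297,64.018,372,18.361,357,17.621,729,35.982
M24,Nagafu No.7,Color,1933,1322,68.391,377,19.503,234,12.106,611,31.609
M25,Nagafu No.36,Color,1904,1201,63.078,464,24.37,239,12.553,703,36.922
M26,Wengao No.1,Color,1871,1254,67.023,379,20.257,238,12.72,617,32.977
M27,Wengao-M No.1,Color,1968,1302,66.159,450,22.866,216,10.976,666,33.841
M28,Wengao No.2,Color,1884,1317,69.904,332,17.622,235,12.473,567,30.096
M29,Wengao-M No.2,Color,1917,1267,66.093,358,18.675,292,15.232,650,33.907
M30,Wengao-M No.3,Color,2066,1270,61.471,438,21.2,358,17.328,796,38.529
M31,Yanfu No.1,Color,1976,1233,62.399,440,22.267,303,15.334,743,37.601
M32,Yanfu No.2,Color,1940,1249,64.381,457,23.557,234,12.062,691,35.619
M33,Yanfu No.3,Color,1952,1278,65.471,449,23.002,225,11.527,674,34.529
M34,Yanfu No.4,Color,1962,1243,63.354,429,21.865,290,14.781,719,36.646
M35,Yanfu No.5,Color,2014,1300,64.548,435,21.599,279,13.853,714,35.452
M36,Yanfu No.8,Color,1915,1233,64.386,445,23.238,237,12.376,682,35.614
M37,Yanfu No.10,Color,1921,1267,65.955,433,22.54,221,11.504,654,34.045
M38,92–58,Color,2103,1383,65.763,440,20.922,280,13.314,720,34.237
M39,Meili,Color,1933,1298,67.15,404,20.9,231,11.95,635,32.85
M40,Meile,Color,2013,1272,63.189,503,24.988,238,11.823,741,36.811
M41,Tianfu No.1,Color,2004,1310,65.369,385,19.212,309,15.419,694,34.631
M42,Tianfu No.2,Color,1980,1270,64.141,462,23.333,248,12.525,710,35.859
M43,Yanchanghong,Color,1947,1259,64.664,446,22.907,242,12.429,688,35.336
M44,Zhaoyuanstripe red Fuji,Color,2021,1304,64.523,458,22.662,259,12.815,717,35.477
M45,Zhaoyuanflush red Fuji,Color,2136,1247,58.38,610,28.558,279,13.062,889,41.62
M46,Shoufu No.1,Color,2031,1281,63.072,517,25.455,233,11.472,750,36.928
M47,Shoufu No.2,Color,2039,1309,64.198,518,25.405,212,10.397,730,35.802
M48,Yulindian Fuji,Color,1978,1242,62.791,493,24.924,243,12.285,736,37.209
M49,Changfujia,Color,2035,1282,62.998,426,20.934,327,16.069,753,37.002
M50,Zhaofuwang,Color,1885,1290,68.435,339,17.984,256,13.581,595,31.565
M51,Yishuihong,Color,1893,1160,61.278,439,23.191,294,15.531,733,38.722
M52,Jihong,Color,1904,1259,66.124,450,23.634,195,10.242,645,33.876
M53,Yannongzaofu,Early-maturation,1793,1141,63.636,423,23.592,229,12.772,652,36.364
M54,Zaoshu Fuji,Early-maturation,1884,1116,59.236,490,26.008,278,14.756,768,40.764
M55,Early Fuji A,Early-maturation,1965,1203,61.221,471,23.969,291,14.809,762,38.779
M56,Hongjiangjun,Early-maturation,1862,1202,64.554,411,22.073,249,13.373,660,35.446
M57,Hongwangjiang,Early-maturation,1804,1222,67.738,301,16.685,281,15.576,582,32.262
M58,Jinfu No.1,Early-maturation,1927,1201,62.325,491,25.48,235,12.195,726,37.675
M59,Gai Fuji,Early-maturation,1851,1169,63.155,405,21.88,277,14.965,682,36.845
M60,Yuhuazaofu,Early-maturation,1816,1149,63.271,391,21.531,276,15.198,667,36.729
M61,Qianxuan No.1,Early-maturation,1847,1220,66.053,408,22.09,219,11.857,627,33.947
M62,Qianxuan No.2,Early-maturation,1889,1226,64.902,450,23.822,213,11.276,663,35.098
M63,Changhong,Early-maturation,1923,1231,64.015,393,20.437,299,15.549,692,35.985
M64,New ryoka,Early-maturation,1884,1219,64.703,411,21.815,254,13.482,665,35.297
M65,Ryoka,Early-maturation,1862,1165,62.567,459,24.651,238,12.782,697,37.433
M66,Jinfu No.2,Early-maturation,1855,1213,65.391,405,21.833,237,12.776,642,34.609
M67,Jinfu No.3,Early-maturation,1892,1217,64.323,381,20.137,294,15.539,675,35.677
M68,Yishuizhongqiu,Early-maturation,1892,1200,63.425,448,23.679,244,12.896,692,36.575
M69,Fengfuji No.1,Early-maturation,1888,1160,61.441,452,23.941,276,14.619,728,38.559
M70,Shoufu No.3,Early-maturation,1928,1232,63.9,472,24.481,224,11.618,696,36.1
M71,Changyanghong,Early-maturation,2057,1458,70.88,340,16.529,259,12.591,599,29.12
M72,Yiyuan Nagafu No.2,Early-maturation,1883,1161,61.657,452,24.004,270,14.339,722,38.343
M73,Hirosaki fuji,Early-maturation,1975,1181,59.797,565,28.608,229,11.595,794,40.203
M74,Karakida Fuji,Early-maturation,2120,1265,59.67,497,23.443,358,16.887,855,40.33
M75,Sufuji,Early-maturation,1867,1201,64.328,381,20.407,285,15.265,666,35.672
M76,Qiufuhong,Spur,2085,1145,54.916,614,29.448,326,15.635,940,45.084
M77,Yanfu No.6,Spur,1818,1235,67.932,367,20.187,216,11.881,583,32.068
M78,Yanfu No.7,Spur,1820,1194,65.604,418,22.967,208,11.429,626,34.396
M79,Huimin spur,Spur,1882,1219,64.772,440,23.379,223,11.849,663,35.228
M80,Duanzhi Fuji,Spur,1852,1222,65.983,390,21.058,240,12.959,630,34.017
M81,Miyazaki,Spur,1853,1200,64.76,399,21.533,254,13.708,653,35.24
M82,Tiaowen Gongqi,Spur,2000,1150,57.5,583,29.15,267,13.35,850,42.5
M83,Aki-fu No.39,Spur,1934,1182,61.117,452,23.371,300,15.512,752,38.883
M84,Longfu,Spur,1853,1198,64.652,399,21.533,256,13.815,655,35.348
M85,Fukushima spur,Spur,1883,1216,64.578,408,21.668,259,13.755,667,35.422
M86,Aomori spur,Spur,1884,1217,64.597,461,24.469,206,10.934,667,35.403
M87,Qinfu No.1,Spur,1941,1241,63.936,445,22.926,255,13.138,700,36.064
M88,Liquan spur,Spur,1840,1177,63.967,411,22.337,252,13.696,663,36.033
M89,Lingbaoduanfu,Spur,1842,1182,64.169,440,23.887,220,11.944,660,35.831
M90,Chengji No.1,Spur,1857,1189,64.028,434,23.371,234,12.601,668,35.972
M91,Yiyuanhong,Spur,1942,1252,64.47,376,19.361,314,16.169,690,35.53
M92,Shifu spur,Spur,1814,1187,65.436,413,22.767,214,11.797,627,34.564
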