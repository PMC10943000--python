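week,sex,p3,p10,p50,p90,p97
22,male,261,321,450,579,639
23,male,344,410,550,690,756
24,male,427,498,650,802,873
25,male,531,609,775,941,1019
26,male,635,719,900,1081,1165
27,male,739,830,1025,1220,1311
28,male,842,940,1150,1360,1458
29,male,977,1084,1312,1541,1648
30,male,1112,1228,1475,1722,1838
31,male,1247,1372,1638,1903,2028
32,male,1382,1515,1800,2085,2218
33,male,1538,1681,1988,2294,2437
34,male,1694,1847,2175,2503,2656
35,male,1850,2013,2362,2712,2875
36,male,2006,2179,2550,2921,3094
37,male,2130,2312,2700,3088,3270
38,male,2255,2444,2850,3256,3445
39,male,2379,2577,3000,3423,3621
40,male,2504,2710,3150,3590,3796
41,male,2545,2754,3200,3646,3855
42,male,2587,2798,3250,3702,3913
22,female,248,307,434,561,621
23,female,328,393,531,669,733
24,female,408,478,627,776,846
25,female,508,585,748,911,987
26,female,609,691,868,1046,1128
27,female,709,798,989,1180,1269
28,female,809,905,1110,1315,1410
29,female,939,1044,1267,1490,1594
30,female,1070,1182,1423,1664,1777
31,female,1200,1321,1580,1839,1961
32,female,1330,1460,1737,2014,2144
33,female,1480,1620,1918,2216,2355
34,female,1631,1780,2099,2418,2567
35,female,1781,1940,2280,2620,2779
36,female,1931,2100,2461,2821,2990
37,female,2052,2228,2606,2983,3159
38,female,2172,2356,2750,3144,3329
39,female,2292,2484,2895,3306,3498
40,female,2412,2612,3040,3467,3667
41,female,2452,2655,3088,3521,3724
42,female,2493,2698,3136,3575,3780
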