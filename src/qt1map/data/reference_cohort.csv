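patient_id,timepoint_id,overlap_class,transformation_class,transformation_percent,mean_qT1_ms
1,TP9,excellent,completely,,2481
1,TP10,excellent,completely,,2482
1,TP11,unevaluable,,,2250
2,TP1,excellent,none,,2158
2,TP2,excellent,completely,,2676
2,TP3,excellent,,,2605
3,TP4,excellent,none,,2772
3,TP5,moderate,none,,2598
3,TP6,moderate,,,2083
4,TP2,moderate,partially,80,2615
4,TP3,excellent,partially,60,3051
4,TP4,excellent,,,3091
5,TP0,excellent,completely,,2076
5,TP1,excellent,completely,,2227
5,TP2,excellent,,,3631
6,TP2,excellent,partially,90,2804
6,TP4,excellent,none,,2776
6,TP5,excellent,,,2955
7,TP3,excellent,none,,2911
7,TP4,excellent,none,,3088
7,TP5,excellent,,,2743
8,TP3,excellent,none,,1994
8,TP4,excellent,none,,2705
8,TP5,moderate,,,1962
9,TP2,moderate,none,,2516
9,TP3,moderate,none,,2928
9,TP4,poor,,,1842
10,TP7,poor,none,,1873
10,TP8,poor,none,,1660
10,TP9,poor,,,1517
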