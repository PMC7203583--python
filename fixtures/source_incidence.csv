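sex,age_lo,age_hi,value
F,50,55,25.04645432383729
F,55,60,39.28065951939694
F,60,65,61.60433697836062
F,65,70,96.61483236220556
F,70,75,151.5222188927369
F,75,80,237.63414226198802
F,80,85,372.68452099798
F,85,90,584.4856756246988
F,90,95,916.656007326669
F,95,,1437.60278619318
M,50,55,18.09345374131471
M,55,60,26.32581985440448
M,60,65,38.3038418709439
M,65,70,55.73176106911656
M,70,75,81.08923387711751
M,75,80,117.98413910917337
M,80,85,171.66590946496683
M,85,90,249.77242445415217
M,90,95,363.4167331891647
M,95,,528.7682267188281
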