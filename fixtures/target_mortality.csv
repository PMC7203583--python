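sex,age_lo,age_hi,value
F,50,55,0.0055795299858791645
F,55,60,0.008971963432591348
F,60,65,0.014427044578930164
F,65,70,0.023198892510680004
F,70,75,0.03730414852312005
F,75,80,0.05998560045029532
F,80,85,0.09645769716878445
F,85,90,0.15510534650418958
F,90,95,0.24941159928468862
F,95,,0.4010573926674144
M,50,55,0.007988872479781532
M,55,60,0.012846220369392156
M,60,65,0.020656904738013643
M,65,70,0.03321659609483728
M,70,75,0.05341275811264916
M,75,80,0.08588847337201375
M,80,85,0.13810988458257772
M,85,90,0.22208265522190782
M,90,95,0.35711206261216777
M,95,,0.5742412667737978
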