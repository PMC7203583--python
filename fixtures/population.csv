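year,sex,age_lo,age_hi,count
2015,F,50,55,96931.68604965946
2015,F,55,60,82169.6116892051
2015,F,60,65,59860.49488764719
2015,F,65,70,54536.913625235764
2015,F,70,75,42481.59331859111
2015,F,75,80,35741.1299344747
2015,F,80,85,29584.530441657498
2015,F,85,90,24537.4030157275
2015,F,90,95,20866.48332413618
2015,F,95,,17658.855859260264
2015,M,50,55,100630.63126378333
2015,M,55,60,81460.154927245
2015,M,60,65,69427.94422878382
2015,M,65,70,55426.75257573321
2015,M,70,75,44017.309858729925
2015,M,75,80,37750.36879738158
2015,M,80,85,32448.835479681045
2015,M,85,90,26137.41108881692
2015,M,90,95,19734.64882456662
2015,M,95,,15734.262571406223
2020,F,50,55,107020.41378923826
2020,F,55,60,90721.89087244969
2020,F,60,65,66090.823275503
2020,F,65,70,60213.15939939933
2020,F,70,75,46903.11167240582
2020,F,75,80,39461.09544533039
2020,F,80,85,32663.712132320063
2020,F,85,90,27091.275630046523
2020,F,90,95,23038.28366847168
2020,F,95,,19496.8037606851
2020,M,50,55,111104.34819224094
2020,M,55,60,89938.5932808691
2020,M,60,65,76654.06042864044
2020,M,65,70,61195.6135025832
2020,M,70,75,48598.66682352981
2020,M,75,80,41679.45750290928
2020,M,80,85,35826.136339310906
2020,M,85,90,28857.81382850957
2020,M,90,95,21788.646925097448
2020,M,95,,17371.89725759788
2030,F,50,55,130457.28723461142
2030,F,55,60,110589.47874488948
2030,F,60,65,80564.3447856978
2030,F,65,70,73399.50531812265
2030,F,70,75,57174.631409053676
2030,F,75,80,48102.85515473828
2030,F,80,85,39816.88282561322
2030,F,85,90,33024.113823566666
2030,F,90,95,28083.53923812333
2030,F,95,,23766.494992007934
2030,M,50,55,135435.5804834963
2030,M,55,60,109634.64335155742
2030,M,60,65,93440.87193245365
2030,M,65,70,74597.11138780473
2030,M,70,75,59241.50367706719
2030,M,75,80,50807.026124455035
2030,M,80,85,43671.8602875914
2030,M,85,90,35177.51403020071
2030,M,90,95,26560.23902092972
2030,M,95,,21176.245821734043
2040,F,50,55,159026.70518664463
2040,F,55,60,134807.9575001491
2040,F,60,65,98207.48674429936
2040,F,65,70,89473.58741316703
2040,F,70,75,69695.55665289341
2040,F,75,80,58637.11201944202
2040,F,80,85,48536.557986007596
2040,F,85,90,40256.2104761995
2040,F,90,95,34233.67762497616
2040,F,95,,28971.22477809102
2040,M,50,55,165095.21687813287
2040,M,55,60,133644.0184836638
2040,M,60,65,113903.90148510574
2040,M,65,70,90933.46252946135
2040,M,70,75,72215.0624144438
2040,M,75,80,61933.481342238556
2040,M,80,85,53235.754001364556
2040,M,85,90,42881.19331210196
2040,M,90,95,32376.783160240346
2040,M,95,,25813.7254931311
2050,F,50,55,193852.66625267113
2050,F,55,60,164330.14796357215
2050,F,60,65,119714.37834301002
2050,F,65,70,109067.80379356377
2050,F,70,75,84958.49465830559
2050,F,75,80,71478.31235630735
2050,F,80,85,59165.79335069524
2050,F,85,90,49072.09594062168
2050,F,90,95,41730.66200074531
2050,F,95,,35315.7613449068
2050,M,50,55,201250.14814226824
2050,M,55,60,162911.3127972624
2050,M,60,65,138848.22032597646
2050,M,65,70,110847.38341421574
2050,M,70,75,88029.75812278013
2050,M,75,80,75496.56816703822
2050,M,80,85,64894.087071876966
2050,M,85,90,52271.935370168794
2050,M,90,95,39467.1180097132
2050,M,95,,31466.787335403224
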