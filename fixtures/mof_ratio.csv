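sex,age_lo,age_hi,value
F,50,55,6.300875117362413
F,55,60,5.105126830596066
F,60,65,4.136301620175847
F,65,70,3.351335169683086
F,70,75,2.7153356913747686
F,75,80,2.200032984928485
F,80,85,1.7825218259930085
F,85,90,1.4442438281191199
F,90,95,1.1701625217958769
F,95,,1.0
M,50,55,6.300875117362413
M,55,60,5.105126830596066
M,60,65,4.136301620175847
M,65,70,3.351335169683086
M,70,75,2.7153356913747686
M,75,80,2.200032984928485
M,80,85,1.7825218259930085
M,85,90,1.4442438281191199
M,90,95,1.1701625217958769
M,95,,1.0
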