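sex,age_lo,age_hi,value
F,50,55,0.005072299987162877
F,55,60,0.008156330393264861
F,60,65,0.013115495071754694
F,65,70,0.021089902282436367
F,70,75,0.033912862293745495
F,75,80,0.054532364045723015
F,80,85,0.08768881560798586
F,85,90,0.14100486045835417
F,90,95,0.2267378175315351
F,95,,0.3645976296976495
M,50,55,0.007608449980744315
M,55,60,0.012234495589897292
M,60,65,0.019673242607632042
M,65,70,0.03163485342365455
M,70,75,0.050869293440618246
M,75,80,0.08179854606858453
M,80,85,0.1315332234119788
M,85,90,0.21150729068753124
M,90,95,0.34010672629730265
M,95,,0.5468964445464741
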