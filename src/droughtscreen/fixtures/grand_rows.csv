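trait,water_regime,grand_mean,sem,cv_pct,lsd_05
PH,WS,14.9,0.44,38.0,0.76
PH,WD,8.37,0.22,34.7,0.79
NT,WS,5.07,0.21,53.7,1.13
NT,WD,3.85,0.17,59.3,0.85
NL,WS,4.82,0.09,24.5,1.25
NL,WD,3.39,0.07,26.6,0.95
RL,WS,75.53,1.27,22.3,5.94
RL,WD,51.72,1.09,27.8,17.31
RWC,WS,74.27,0.79,14.05,3.45
RWC,WD,10.46,0.54,68.05,7.12
Phi2,WS,0.36,0.01,35.25,0.104
Phi2,WD,0.18,0.01,44.05,0.082
PhiNPQ,WS,0.6,0.01,24.06,0.16
PhiNPQ,WD,0.77,0.01,13.48,0.1
SPAD,WS,37.14,0.38,13.53,3.46
SPAD,WD,5.44,0.3,73.89,2.31
FvFm,WS,0.41,0.01,28.91,0.14
FvFm,WD,0.23,0.0,39.76,0.27
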