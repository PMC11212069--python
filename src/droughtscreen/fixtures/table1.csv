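ecotype,trait,water_regime,mean,sem
CIAT16449,PH,WS,8.66,0.21
CIAT16449,PH,WD,5.6,0.25
CIAT16449,NT,WS,2.6,0.6
CIAT16449,NT,WD,1.4,0.25
CIAT16449,NL,WS,4.4,0.4
CIAT16449,NL,WD,2.8,0.37
CIAT16449,RL,WS,54.8,0.2
CIAT16449,RL,WD,44.4,2.25
CIAT16514,PH,WS,25.04,0.16
CIAT16514,PH,WD,10.4,0.25
CIAT16514,NT,WS,4.6,0.25
CIAT16514,NT,WD,6.2,0.37
CIAT16514,NL,WS,4.2,0.37
CIAT16514,NL,WD,3.2,0.8
CIAT16514,RL,WS,90.8,0.2
CIAT16514,RL,WD,42.4,5.06
CIAT6384,PH,WS,11.0,0.32
CIAT6384,PH,WD,8.4,0.25
CIAT6384,NT,WS,3.0,0.45
CIAT6384,NT,WD,2.8,0.37
CIAT6384,NL,WS,5.4,0.51
CIAT6384,NL,WD,2.8,0.37
CIAT6384,RL,WS,85.0,1.67
CIAT6384,RL,WD,57.4,5.99
CIAT6385,PH,WS,8.6,0.25
CIAT6385,PH,WD,7.8,0.26
CIAT6385,NT,WS,1.2,0.2
CIAT6385,NT,WD,2.0,0.0
CIAT6385,NL,WS,3.2,0.2
CIAT6385,NL,WD,3.0,0.45
CIAT6385,RL,WS,111.2,0.58
CIAT6385,RL,WD,55.2,13.9
CIAT6399,PH,WS,17.46,0.16
CIAT6399,PH,WD,4.6,0.25
CIAT6399,NT,WS,7.2,0.2
CIAT6399,NT,WD,5.0,0.32
CIAT6399,NL,WS,5.4,0.4
CIAT6399,NL,WD,2.6,0.25
CIAT6399,RL,WS,90.6,0.25
CIAT6399,RL,WD,48.2,4.74
CIAT6426,PH,WS,15.7,0.26
CIAT6426,PH,WD,6.5,0.22
CIAT6426,NT,WS,2.2,0.49
CIAT6426,NT,WD,1.8,0.37
CIAT6426,NL,WS,4.4,0.24
CIAT6426,NL,WD,3.2,0.2
CIAT6426,RL,WS,76.6,0.93
CIAT6426,RL,WD,49.2,6.06
CIAT6684,PH,WS,10.82,0.23
CIAT6684,PH,WD,9.0,0.27
CIAT6684,NT,WS,3.0,0.0
CIAT6684,NT,WD,1.2,0.2
CIAT6684,NL,WS,4.2,0.74
CIAT6684,NL,WD,3.2,0.2
CIAT6684,RL,WS,51.0,0.45
CIAT6684,RL,WD,47.8,3.18
Basilisk,PH,WS,18.5,0.22
Basilisk,PH,WD,7.8,0.3
Basilisk,NT,WS,11.8,0.2
Basilisk,NT,WD,4.8,0.2
Basilisk,NL,WS,5.8,0.37
Basilisk,NL,WD,2.8,0.2
Basilisk,RL,WS,79.6,4.89
Basilisk,RL,WD,57.0,4.09
Busia,PH,WS,13.9,0.19
Busia,PH,WD,7.9,0.18
Busia,NT,WS,7.6,0.25
Busia,NT,WD,6.6,0.25
Busia,NL,WS,6.2,0.49
Busia,NL,WD,4.0,0.0
Busia,RL,WS,55.4,0.25
Busia,RL,WD,54.8,5.42
K1,PH,WS,24.1,0.4
K1,PH,WD,11.5,0.32
K1,NT,WS,4.6,0.25
K1,NT,WD,3.4,0.4
K1,NL,WS,5.8,0.37
K1,NL,WD,4.6,0.4
K1,RL,WS,80.0,0.32
K1,RL,WD,43.4,4.28
K2,PH,WS,16.6,0.37
K2,PH,WD,12.2,0.52
K2,NT,WS,6.6,0.25
K2,NT,WD,6.8,0.37
K2,NL,WS,4.4,0.25
K2,NL,WD,2.8,0.37
K2,RL,WS,77.0,0.45
K2,RL,WD,43.6,9.41
K3,PH,WS,12.8,0.12
K3,PH,WD,11.0,0.61
K3,NT,WS,3.2,0.2
K3,NT,WD,2.0,0.32
K3,NL,WS,4.0,0.32
K3,NL,WD,4.4,0.4
K3,RL,WS,74.4,0.25
K3,RL,WD,53.2,7.08
K4,PH,WS,15.46,0.17
K4,PH,WD,11.6,0.29
K4,NT,WS,3.4,0.25
K4,NT,WD,2.4,0.25
K4,NL,WS,4.2,0.37
K4,NL,WD,3.6,0.25
K4,RL,WS,82.0,0.0
K4,RL,WD,50.2,6.64
K5,PH,WS,12.56,0.25
K5,PH,WD,5.2,0.2
K5,NT,WS,2.8,0.2
K5,NT,WD,1.4,0.25
K5,NL,WS,4.0,0.32
K5,NL,WD,2.4,0.4
K5,RL,WS,50.6,0.4
K5,RL,WD,55.0,1.48
K6,PH,WS,18.0,0.27
K6,PH,WD,6.4,0.25
K6,NT,WS,4.2,0.86
K6,NT,WD,5.0,0.32
K6,NL,WS,5.2,0.92
K6,NL,WD,3.0,0.45
K6,RL,WS,72.6,4.37
K6,RL,WD,53.0,4.72
K7,PH,WS,29.9,0.33
K7,PH,WD,12.5,0.22
K7,NT,WS,6.6,0.25
K7,NT,WD,3.8,0.2
K7,NL,WS,5.2,0.58
K7,NL,WD,4.2,0.2
K7,RL,WS,87.2,0.37
K7,RL,WD,62.6,3.47
K8,PH,WS,12.54,0.23
K8,PH,WD,6.6,0.25
K8,NT,WS,5.0,0.71
K8,NT,WD,4.2,0.2
K8,NL,WS,6.0,0.55
K8,NL,WD,2.8,0.2
K8,RL,WS,97.0,0.55
K8,RL,WD,51.0,2.3
K9,PH,WS,11.54,0.25
K9,PH,WD,6.5,0.32
K9,NT,WS,2.8,0.2
K9,NT,WD,2.2,0.37
K9,NL,WS,5.0,0.55
K9,NL,WD,2.8,0.49
K9,RL,WS,121.8,6.21
K9,RL,WD,53.0,11.6
K10,PH,WS,22.0,0.55
K10,PH,WD,7.6,0.25
K10,NT,WS,5.6,0.25
K10,NT,WD,4.4,0.25
K10,NL,WS,5.8,0.37
K10,NL,WD,3.6,0.4
K10,RL,WS,68.2,0.49
K10,RL,WD,69.2,4.22
K12,PH,WS,16.3,0.37
K12,PH,WD,7.7,9.2
K12,NT,WS,3.8,0.2
K12,NT,WD,1.4,0.25
K12,NL,WS,4.2,0.2
K12,NL,WD,3.6,0.25
K12,RL,WS,87.4,0.4
K12,RL,WD,42.0,3.89
K13,PH,WS,7.08,0.11
K13,PH,WD,5.2,0.37
K13,NT,WS,2.2,0.2
K13,NT,WD,2.2,0.2
K13,NL,WS,4.6,0.25
K13,NL,WD,2.8,0.37
K13,RL,WS,53.0,6.2
K13,RL,WD,55.4,8.62
K15,PH,WS,7.64,0.09
K15,PH,WD,4.6,0.19
K15,NT,WS,7.2,0.2
K15,NT,WD,9.0,0.0
K15,NL,WS,4.8,0.58
K15,NL,WD,4.6,0.4
K15,RL,WS,55.6,0.25
K15,RL,WD,50.6,5.62
K16,PH,WS,11.62,0.18
K16,PH,WD,8.8,0.12
K16,NT,WS,3.0,0.71
K16,NT,WD,2.0,0.45
K16,NL,WS,4.8,0.66
K16,NL,WD,3.2,0.49
K16,RL,WS,84.8,1.24
K16,RL,WD,49.0,7.63
K17,PH,WS,21.2,0.37
K17,PH,WD,15.8,0.26
K17,NT,WS,5.8,0.2
K17,NT,WD,4.2,0.37
K17,NL,WS,4.6,0.25
K17,NL,WD,4.0,0.32
K17,RL,WS,71.8,3.81
K17,RL,WD,62.0,6.31
K18,PH,WS,14.72,0.19
K18,PH,WD,5.7,0.3
K18,NT,WS,4.0,0.0
K18,NT,WD,1.6,0.45
K18,NL,WS,5.0,0.32
K18,NL,WD,3.4,0.25
K18,RL,WS,68.6,0.25
K18,RL,WD,63.2,10.9
K19,PH,WS,17.5,0.22
K19,PH,WD,11.5,0.32
K19,NT,WS,8.4,0.25
K19,NT,WD,3.2,0.37
K19,NL,WS,5.6,0.25
K19,NL,WD,3.6,0.25
K19,RL,WS,75.2,0.37
K19,RL,WD,52.6,6.53
K20,PH,WS,7.8,0.2
K20,PH,WD,6.4,0.25
K20,NT,WS,2.4,0.25
K20,NT,WD,1.8,0.37
K20,NL,WS,5.0,0.32
K20,NL,WD,3.8,0.37
K20,RL,WS,62.2,0.2
K20,RL,WD,53.6,8.39
K21,PH,WS,19.6,0.25
K21,PH,WD,11.6,0.25
K21,NT,WS,3.4,0.25
K21,NT,WD,2.8,0.2
K21,NL,WS,4.0,0.32
K21,NL,WD,3.2,0.2
K21,RL,WS,74.4,0.25
K21,RL,WD,45.8,4.45
K22,PH,WS,24.5,0.22
K22,PH,WD,11.6,0.25
K22,NT,WS,5.0,0.95
K22,NT,WD,5.2,0.2
K22,NL,WS,5.6,0.25
K22,NL,WD,3.4,0.25
K22,RL,WS,58.4,0.25
K22,RL,WD,47.8,2.6
K23,PH,WS,8.12,0.2
K23,PH,WD,5.5,0.32
K23,NT,WS,10.6,0.25
K23,NT,WD,9.0,0.32
K23,NL,WS,5.6,0.4
K23,NL,WD,4.2,0.2
K23,RL,WS,61.4,1.66
K23,RL,WD,63.6,7.35
Kakamega,PH,WS,11.2,0.52
Kakamega,PH,WD,8.6,0.19
Kakamega,NT,WS,5.6,0.25
Kakamega,NT,WD,4.8,0.37
Kakamega,NL,WS,3.6,0.25
Kakamega,NL,WD,3.0,0.0
Kakamega,RL,WS,85.4,1.86
Kakamega,RL,WD,47.6,2.5
Kisii,PH,WS,11.9,0.19
Kisii,PH,WD,6.8,0.26
Kisii,NT,WS,11.6,0.4
Kisii,NT,WD,9.0,0.32
Kisii,NL,WS,5.2,0.37
Kisii,NL,WD,3.6,0.25
Kisii,RL,WS,69.0,0.2
Kisii,RL,WD,42.2,1.24
Lanet,PH,WS,20.0,0.35
Lanet,PH,WD,13.0,0.16
Lanet,NT,WS,6.6,0.25
Lanet,NT,WD,3.8,0.37
Lanet,NL,WS,5.6,0.25
Lanet,NL,WD,4.2,0.2
Lanet,RL,WS,95.2,0.74
Lanet,RL,WD,44.6,4.52
Piata,PH,WS,6.4,0.29
Piata,PH,WD,4.6,0.25
Piata,NT,WS,4.2,0.2
Piata,NT,WD,3.0,0.32
Piata,NL,WS,4.0,0.95
Piata,NL,WD,3.6,0.25
Piata,RL,WS,69.8,0.2
Piata,RL,WD,36.0,1.26
Toledo,PH,WS,11.0,0.16
Toledo,PH,WD,6.4,0.24
Toledo,NT,WS,5.8,0.97
Toledo,NT,WD,4.2,0.37
Toledo,NL,WS,3.6,0.4
Toledo,NL,WD,2.8,0.2
Toledo,RL,WS,67.4,2.94
Toledo,RL,WD,63.4,3.41
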