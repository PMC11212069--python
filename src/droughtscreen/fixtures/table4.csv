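ecotype,PC1,PC2,PC3,PC4,ranking_value,numerical_rank
K17,2.89,0.74,1.0,1.88,159.94,1
Kisii,4.25,1.15,-0.1,-2.53,153.82,2
Busia,2.6,1.61,-0.85,-0.24,119.42,3
K7,3.02,-0.98,0.61,1.47,113.17,4
Kakamega,1.86,2.03,0.11,-1.02,107.16,5
K1,2.74,-1.39,1.78,0.49,98.43,6
Lanet,1.59,0.5,0.96,0.87,94.25,7
K23,1.27,2.43,-2.1,0.71,83.12,8
K15,2.01,1.27,-1.62,-0.47,75.91,9
K3,1.86,-1.56,0.68,1.82,61.6,10
CIAT16514,0.24,1.34,1.21,-1.04,46.66,11
K2,-0.24,0.52,2.72,-0.3,39.43,12
K10,0.29,1.52,-1.45,1.02,38.11,13
K19,0.55,-0.37,-0.27,1.06,19.57,14
K4,1.09,-1.59,0.84,-0.31,10.43,15
Toledo,-1.1,2.09,-0.47,0.08,3.94,16
K21,0.07,-1.43,1.85,0.03,-4.84,17
K6,-0.87,0.93,-0.03,-0.2,-12.2,18
K22,-3.91,3.42,2.17,1.29,-15.59,19
Basilisk,-0.62,0.85,-0.08,-1.11,-16.01,20
K8,-0.87,0.06,0.42,-0.39,-29.03,21
CIAT6399,-1.16,1.18,-0.79,-0.96,-36.72,22
K12,-0.39,-1.58,0.15,-0.07,-50.94,23
Piata,-0.06,-1.03,-0.68,-1.6,-55.15,24
CIAT6426,0.04,-2.58,0.42,-0.84,-64.36,25
K16,-1.37,-1.0,-0.01,0.6,-67.74,26
K20,-0.18,-1.92,-1.42,0.47,-67.85,27
K18,-0.33,-1.7,-2.46,1.46,-71.98,28
CIAT6684,-0.62,-2.19,0.1,-0.8,-83.25,29
CIAT6384,-1.66,-0.89,0.13,-0.78,-89.45,30
K13,-0.82,-1.46,-1.6,-0.36,-92.26,31
CIAT6385,-2.89,-0.36,-0.01,0.56,-108.81,32
CIAT16449,-2.53,-1.36,0.36,0.32,-116.87,33
K5,-1.96,-1.3,-1.94,0.6,-124.42,34
K9,-4.8,1.5,0.4,0.76,-125.83,35
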