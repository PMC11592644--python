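residue,physchem1,physchem2,physchem3,physchem4,physchem5,physchem6,physchem7,physchem8,physchem9,physchem10,physchem11,physchem12
A,-0.041,-0.95,1.408,-1.217,0.844,0.174,0.824,-0.292,1.83,2.837,-0.515,-0.254
C,-0.027,0.255,0.567,1.169,1.174,0.225,0.514,-1.136,0.8,-1.335,0.675,-0.18
D,-1.726,-0.196,-0.468,-1.063,-0.974,-0.474,-0.312,-1.413,-1.241,-0.469,-2.02,-2.197
E,-0.619,-0.665,-0.674,0.537,-1.425,-0.556,-0.151,-0.715,-1.567,0.581,-2.832,-2.186
F,1.507,0.33,-1.676,2.021,0.68,1.569,-0.639,0.149,-0.91,0.555,0.829,0.241
G,-1.546,-1.094,1.344,-0.815,1.326,-0.589,-0.939,-1.742,1.314,0.073,0.911,-0.264
H,-0.283,0.311,-0.681,0.279,-0.992,-0.341,-1.366,0.563,-0.601,0.042,-0.231,0.491
I,0.684,-0.601,0.475,-1.022,1.078,1.466,2.023,0.834,0.894,0.599,0.682,0.136
K,-0.117,-1.069,-0.437,0.322,-0.583,-1.501,-0.714,1.406,-0.25,0.622,-0.106,1.826
L,0.93,-0.87,0.346,-0.396,0.495,1.14,1.893,0.721,1.026,1.166,0.473,-0.03
M,1.286,-1.114,-0.309,0.941,0.153,0.546,1.207,0.398,0.281,0.861,-0.632,-0.167
N,-1.314,1.386,0.37,-1.002,-0.562,-1.066,-0.332,-0.557,-0.352,-1.286,-0.297,-0.145
P,-0.866,-1.499,0.373,-0.125,-0.459,-0.611,-0.742,-1.125,0.622,-0.298,1.108,-0.167
Q,-0.048,1.238,0.249,-0.395,-0.246,-0.834,-0.057,0.375,-0.814,-0.85,-0.964,-0.077
R,0.293,1.869,0.779,1.541,-1.953,-1.787,-0.562,2.11,-0.171,-0.962,0.151,2.477
S,-0.988,-0.002,0.846,0.2,0.42,-0.721,-0.417,-1.178,0.669,-0.279,0.138,-0.24
T,-0.398,0.226,0.676,-0.428,0.957,-0.273,-0.084,-0.478,0.096,-0.859,0.146,-0.093
V,0.366,-0.409,0.902,-1.843,1.705,1.412,1.767,0.581,1.157,0.633,0.542,0.134
W,2.097,1.151,-1.971,1.241,-1.147,1.168,-0.845,1.022,-1.731,-0.309,0.873,0.478
Y,0.812,1.705,-2.119,0.057,-0.489,1.052,-1.069,0.479,-1.053,-1.321,1.068,0.216
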