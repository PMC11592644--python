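residue,kidera1,kidera2,kidera3,kidera4,kidera5,kidera6,kidera7,kidera8,kidera9,kidera10
A,-1.685,0.881,-1.006,-0.153,0.153,0.794,-1.081,1.172,1.563,-2.44
C,-0.351,-0.798,0.533,-0.633,1.083,-0.662,-0.277,0.808,0.287,0.404
D,-1.224,-0.376,-0.574,1.454,-0.127,2.117,-0.771,-1.288,-0.533,-0.366
E,-1.354,-0.691,-1.372,2.054,-1.234,2.925,-0.755,-0.976,0.023,-0.064
F,0.473,-1.724,0.655,-1.257,-1.263,0.086,-0.738,-1.26,-0.078,0.66
G,0.195,1.161,1.043,-0.282,2.159,-0.061,-1.774,0.83,0.161,-0.469
H,0.766,0.53,1.035,0.566,-0.572,-0.024,0.113,-0.369,-0.951,0.474
I,-0.623,-0.094,-1.535,-1.576,-0.547,-0.719,0.309,-0.1,1.372,-1.113
K,2.358,1.958,1.113,0.962,-0.136,-0.197,1.086,0.558,0.277,0.898
L,-1.275,0.011,-1.707,-1.168,-0.619,-0.382,0.051,0.042,1.525,-0.809
M,-0.739,-0.569,-1.212,0.036,-1.007,0.307,-0.077,-0.035,1.511,-0.055
N,0.096,0.306,0.725,0.716,1.039,0.031,0.867,0.33,-1.205,0.01
P,-0.285,1.213,0.535,0.001,1.518,-0.22,-1.173,-0.182,-0.011,1.087
Q,0.771,-0.408,-0.275,0.993,-0.042,0.181,1.11,0.472,-0.752,-0.089
R,1.676,1.499,1.325,1.154,0.006,-1.107,2.93,2.077,-1.511,1.394
S,-0.264,0.44,0.769,0.244,1.328,0.228,-0.6,0.917,-0.145,-0.071
T,0.771,-0.154,0.187,-0.035,0.838,-0.266,-0.054,0.509,-0.165,-0.181
V,-0.298,-0.031,-1.287,-1.544,-0.214,-0.824,0.077,0.183,1.305,-1.87
W,0.516,-1.702,0.051,-0.617,-1.55,-0.584,0.419,-1.896,-1.162,1.545
Y,0.476,-1.452,0.998,-0.913,-0.815,-1.624,0.338,-1.794,-1.512,1.053
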