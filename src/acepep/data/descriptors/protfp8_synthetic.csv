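residue,protfp1,protfp2,protfp3,protfp4,protfp5,protfp6,protfp7,protfp8
A,-0.616,1.154,0.007,-0.601,-1.022,1.289,-0.619,-1.42
C,0.103,0.98,-0.651,0.458,-0.015,0.058,-0.346,-0.267
D,2.042,-0.854,-0.324,-2.308,0.623,1.418,-1.157,2.084
E,1.656,-1.472,1.277,-2.607,0.134,1.466,-0.88,2.168
F,0.098,-0.398,1.762,-0.079,-1.605,-0.535,0.247,-0.43
G,-0.526,0.985,-1.91,0.149,0.347,0.055,-2.179,-0.3
H,0.124,-1,0.014,-0.044,0.247,-0.704,0.045,0.702
I,-0.816,1.368,0.122,1.113,-1.317,0.871,1.219,-1.433
K,-2.148,-0.384,0.301,0.336,1.149,-1.122,0.326,0.473
L,-1.008,0.742,0.462,0.638,-1.299,1.007,0.986,-1.473
M,-0.745,0.084,1.48,-0.058,-0.899,1.001,0.446,-0.34
N,1.107,-0.044,-1.292,-0.587,1.548,-0.456,-0.076,0.778
P,-0.972,-0.581,-1.235,0.504,0.6,0.066,-1.379,-0.099
Q,1.011,-0.051,0.125,-0.409,1.013,-0.536,0.312,0.793
R,-0.781,-0.787,-0.192,1.709,1.891,-2.453,2.002,0.169
S,0.114,0.423,-1.068,-0.345,0.595,-0.071,-1.062,0.124
T,0.281,0.799,-0.641,0.277,0.438,-0.272,-0.523,0.149
V,-0.517,1.96,-0.28,1.108,-1.274,0.894,0.798,-1.465
W,0.561,-1.788,1.919,0.627,-0.735,-1.06,1.099,-0.273
Y,1.032,-1.136,0.124,0.121,-0.419,-0.916,0.742,0.058
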