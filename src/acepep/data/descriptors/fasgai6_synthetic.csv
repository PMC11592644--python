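residue,fasgai1,fasgai2,fasgai3,fasgai4,fasgai5,fasgai6
A,-0.377,0.061,1.395,-1.042,0.589,-0.169
C,-0.309,0.462,-0.474,-0.781,0.723,1.801
D,1.516,-1.951,-2.033,0.866,-1.026,-1.534
E,1.98,-2.683,-0.846,1.081,-1.036,-1.787
F,0.994,0.253,0.14,0.373,1.074,0.953
G,-1.314,0.101,-1.004,-2.018,-0.124,0.081
H,0.196,-0.368,-0.069,-0.244,-1.031,-1.159
I,-0.296,1.642,0.926,0.935,1.744,0.928
K,-1.815,-0.152,1.203,-0.602,-1.664,-1.815
L,-0.053,1.264,1.144,0.542,1.37,0.931
M,0.306,-0.071,1.238,0.711,0.455,0.673
N,-0.133,-0.432,-1.153,-0.262,-0.841,-0.562
P,-0.874,0.197,-1.108,-1.297,-0.703,0.346
Q,0.241,-0.824,0.042,0.806,-0.397,-0.684
R,-1.33,0.228,1.46,-1.1,-1.39,-0.728
S,-0.538,-0.314,-0.653,-1.435,-0.309,0.134
T,-0.482,-0.042,-0.38,-0.06,0.256,0.186
V,-0.511,1.573,0.928,0.832,1.8,0.752
W,1.447,0.249,0.065,1.55,0.425,0.954
Y,1.351,0.807,-0.823,1.145,0.085,0.7
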