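residue,atchley1,atchley2,atchley3,atchley4,atchley5
A,0.261,-1.31,0.054,-0.849,0.583
C,-1.018,0.214,-0.073,0.392,-0.353
D,1.667,1.667,1.978,0.672,1.82
E,2.127,0.943,2.383,-0.285,0.884
F,-1.197,-0.875,0.051,-1.124,0.457
G,-0.331,0.831,0.55,1.967,1.311
H,0.843,0.443,0.272,0.223,0.049
I,-1.391,-1.34,-1.591,-1.297,-0.35
K,0.55,0.589,-0.304,-0.082,-1.26
L,-1.118,-1.641,-0.895,-1.316,-0.557
M,-0.366,-1.183,0.091,-1.521,-0.796
N,0.828,1.413,0.171,1.088,0.272
P,-0.431,0.443,0.918,1.719,0.537
Q,0.998,0.667,-0.214,0.249,-0.458
R,1.159,0.453,-1.321,0.06,-3.138
S,0.175,0.778,0.609,1.066,0.34
T,-0.136,0.591,-0.326,0.775,0.177
V,-1.203,-1.181,-1.817,-1.062,0.143
W,-0.672,-1.174,-0.24,-0.774,-0.157
Y,-0.746,-0.328,-0.297,0.099,0.496
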