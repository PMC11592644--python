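residue,blosum_pc1,blosum_pc2,blosum_pc3,blosum_pc4,blosum_pc5,blosum_pc6,blosum_pc7,blosum_pc8,blosum_pc9,blosum_pc10
A,-1.114,-0.351,-2.039,1.199,0.881,0.702,-0.178,-0.054,-0.124,0.902
C,-0.839,-0.153,1.146,-0.263,0.625,1.127,0.421,-0.26,0.154,-1.411
D,0.429,-1.507,0.555,2.082,-0.908,-0.993,-1.381,-2.036,2.008,-1.188
E,1.099,-2.093,0.184,2.127,-0.077,-1.041,-2.114,-1.163,1.646,-0.965
F,-0.443,0.432,0.913,-0.162,1.039,0.505,-1.077,1.608,-0.992,1.707
G,-1.29,-0.087,-1.219,-0.549,1.543,0.975,1.092,-1.155,1.109,-0.938
H,0.818,0.659,0.049,-0.022,0.278,-0.878,0.259,0.392,0.202,0.653
I,-1.283,-0.159,-0.547,0.312,-1.963,0.741,-0.367,0.689,-1.442,-0.133
K,1.322,-0.654,-1.726,-1.414,1.009,-1.535,1.464,0.742,-0.441,0.644
L,-0.946,-0.336,-0.828,0.497,-1.083,1.136,-0.543,0.537,-1.403,-0.101
M,-0.055,-1.484,-0.241,0.502,-0.051,0.799,-0.865,0.807,-0.764,-0.026
N,0.586,0.645,0.761,0.042,-0.321,-1.144,0.747,-1.367,1.031,-0.477
P,-0.371,-0.268,-0.745,-0.929,1.004,1.382,0.739,-1.207,0.439,-1.263
Q,1.008,0.198,0.525,-0.197,-0.566,-1.283,0.063,-0.154,0.656,0.089
R,2.2,2.184,0.607,-2.099,0.584,-1.958,2.162,0.889,-0.679,-0.089
S,-0.35,0.027,-0.104,-0.079,1.286,0.237,0.68,-0.952,0.881,-0.902
T,-0.316,-0.013,0.115,-0.559,-0.089,-0.073,0.427,-0.259,0.553,-0.518
V,-1.591,-0.033,-0.725,0.391,-2.024,0.576,-0.135,0.68,-1.049,0.254
W,0.8,1.372,1.599,-0.959,-0.265,0.4,-1.054,1.488,-1.22,2.135
Y,0.336,1.619,1.721,0.08,-0.903,0.324,-0.341,0.777,-0.567,1.626
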