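residue,vsw1,vsw2,vsw3,vsw4,vsw5,vsw6,vsw7
A,-0.223,0.092,0.885,-1.395,-1.716,-0.518,-0.198
C,0.003,-0.763,0.941,0.886,-0.296,0.995,0.664
D,-0.275,2.144,-1.172,-1.725,0.211,1.959,1.676
E,0.014,2.381,-1.549,-2.839,0.018,1.129,1.171
F,1.71,-1.436,-1.75,-0.112,0.528,-0.306,-0.235
G,-1.033,-0.958,0.994,0.443,-0.824,1.035,1.137
H,-0.018,-0.512,-0.602,0.194,0.869,-0.396,-0.725
I,0.776,-0.225,-0.016,0.443,-1.295,-0.761,0.34
K,-1.397,0.544,0.166,0.935,0.501,-1.923,-0.943
L,0.826,-0.001,0.284,-0.154,-1.45,-0.877,0.276
M,0.758,0.923,-0.218,-0.718,-0.868,-0.749,0.277
N,-1.136,0.555,0.747,0.392,0.921,0.994,-0.187
P,-0.365,-0.446,0.965,0.441,-0.476,0.435,1.459
Q,-0.761,1.062,-0.024,-0.293,0.818,0.273,-0.903
R,-1.502,-1.403,1.903,1.571,1.701,-1.843,-2.736
S,-0.87,-0.435,0.986,0.125,-0.172,0.88,0.428
T,-0.586,-0.009,0.229,0.407,0.028,0.616,0.154
V,0.504,-0.212,0.002,0.482,-1.326,-0.519,0.14
W,1.977,-0.745,-1.47,-0.109,1.437,-0.731,-0.929
Y,1.597,-0.559,-1.301,1.025,1.391,0.306,-0.867
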