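residue,dpps1,dpps2,dpps3,dpps4,dpps5,dpps6,dpps7,dpps8,dpps9,dpps10
A,-1.838,1.732,0.049,-0.502,1.519,0.131,1.388,-0.545,0.693,0.18
C,-0.103,-0.609,0.38,0.546,0.122,1.091,0.372,1.444,1.131,-0.566
D,0.738,-1.7,-0.69,-2.245,0.29,0.995,-1.092,-0.511,0.052,1.566
E,1.178,-0.257,-1.603,-2.62,0.27,0.496,-1.197,-0.288,-0.107,1.784
F,-0.522,0.673,-1.364,0.558,-1.086,0.707,-1.535,1.549,-1.914,-0.951
G,-0.979,-0.543,1.697,0.613,-0.002,1.293,-0.273,-1.415,1.289,0.346
H,0.527,-0.065,0.22,0.272,-1.046,-0.459,-0.503,-0.896,-1.035,0.767
I,-1.44,0.795,-0.042,-0.405,1.205,-0.111,1.186,1.324,0.103,-1.761
K,0.998,1.199,1.487,0.975,0.393,-1.963,-0.543,-1.753,-0.38,0.742
L,-1.179,1.396,-0.205,-0.529,1.018,-0.098,1.003,0.976,0.144,-1.486
M,-0.07,1.579,-0.741,-0.708,1.086,0.048,0.041,1.018,0.198,-0.532
N,0.781,-1.78,0.463,0.163,-0.146,-0.364,0.411,-0.547,0.456,0.928
P,-0.027,-0.144,1.541,0.305,-0.794,0.805,-1.144,-1.499,0.88,-0.031
Q,1.055,-0.868,-0.666,-0.064,0.26,-0.789,0.623,-0.182,0.324,0.777
R,1.794,0.279,1.114,1.887,-1.422,-3.026,1.635,-0.646,0.29,0.824
S,-0.062,-0.558,0.816,0.34,-0.083,0.575,0.138,-0.429,0.965,0.593
T,0.011,-0.82,0.254,0.326,0.29,0.299,0.264,-0.034,0.781,0.051
V,-1.815,0.487,0.05,-0.261,1.583,0.082,1.542,1.051,0.325,-1.498
W,0.534,0.255,-1.829,0.609,-1.965,-0.22,-1.496,0.773,-2.022,-0.949
Y,0.418,-1.051,-0.931,0.74,-1.492,0.507,-0.819,0.61,-2.171,-0.785
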