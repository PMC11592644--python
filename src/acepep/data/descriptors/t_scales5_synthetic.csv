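residue,t_scales1,t_scales2,t_scales3,t_scales4,t_scales5
A,0.415,0.314,2.012,0.627,1.705
C,-1.25,-0.338,0.537,0.378,-0.181
D,-0.215,0.218,-0.842,1.842,0.951
E,0.713,1.54,-1.07,1.71,1.368
F,-0.532,-0.625,0.405,0.049,-1.604
G,-0.646,0.653,2.074,0.489,-0.112
H,0.863,0.375,-0.389,-0.516,-0.85
I,-1.111,-1.07,0.209,0.23,0.736
K,2.825,1.829,-0.055,-1.811,-0.272
L,-0.769,-0.191,0.356,0.225,1.001
M,0.341,0.982,-0.003,0.304,0.928
N,0.084,-0.945,-0.663,-0.156,0.024
P,-0.81,1.625,0.915,-0.05,-0.217
Q,0.88,-0.579,-1.223,-0.228,0.225
R,1.787,0.493,-1.441,-2.858,-0.659
S,-0.229,0.348,0.903,0.247,0.113
T,-0.229,-0.438,0.121,0.138,-0.102
V,-0.969,-1.57,0.595,0.41,0.77
W,-0.515,-0.765,-1.268,-0.779,-1.772
Y,-0.634,-1.856,-1.173,-0.251,-2.052
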