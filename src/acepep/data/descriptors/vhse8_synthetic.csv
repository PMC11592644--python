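residue,vhse1,vhse2,vhse3,vhse4,vhse5,vhse6,vhse7,vhse8
A,0.335,1.592,1.812,1.175,-0.307,-0.053,-2.174,-0.304
C,-0.167,0.997,-0.384,-0.833,0.17,-0.159,0.068,0.79
D,1.466,-0.404,-1.503,0.025,1.546,1.599,0.053,-1.357
E,1.344,-0.089,-1.381,1.348,0.635,1.538,0.325,-1.97
F,-1.543,0.417,-0.738,0.438,0.012,-1.872,-0.399,0.973
G,1.551,1.059,0.893,-1.763,1.768,-0.388,-1.023,-0.03
H,0.248,-1.03,0.242,-0.304,0.457,0.325,0.541,-0.481
I,-1.036,0.801,0.449,1.166,-1.416,-1.032,-0.62,1.682
K,0.547,-0.983,1.596,-0.573,-0.922,-0.226,2.113,-1.269
L,-0.697,1.156,0.368,1.485,-1.411,-0.751,-0.695,1.178
M,-0.238,0.966,-0.055,1.545,-1.582,-0.573,0.165,0.075
N,0.292,-1.037,-0.318,-1.22,0.973,1.521,0.444,-0.722
P,1.649,0.637,-0.159,-1.094,1.314,-0.286,0.215,-0.04
Q,-0.2,-1.12,-0.27,-0.125,-0.308,1.05,0.342,-0.868
R,-0.61,-2.063,1.381,-0.398,-0.889,1.627,2.493,-0.811
S,0.791,0.535,0.32,-1.06,1.075,0.532,-0.215,-0.41
T,0.159,-0.05,0.052,-0.813,0.274,-0.054,-0.169,0.071
V,-0.941,0.73,0.892,0.827,-1.213,-1.055,-1.252,1.621
W,-1.625,-0.975,-1.629,0.825,-0.336,-1.201,0.063,0.761
Y,-1.322,-1.139,-1.567,-0.652,0.161,-0.542,-0.276,1.112
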