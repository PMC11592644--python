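residue,hese1,hese2,hese3,hese4,hese5,hese6
A,-1.437,1.739,-0.761,-0.119,0.536,-0.002
C,-0.385,-0.53,0.161,-0.208,-0.933,-0.628
D,1.985,0.792,-0.434,1.847,1.374,-1.814
E,1.613,0.614,-1.457,1.517,2.183,-1.852
F,0.766,-1.573,-0.783,-1.438,-1.379,1.334
G,-0.665,-0.154,1.429,0.782,-0.696,-0.458
H,0.394,-0.418,0.481,-0.439,-0.279,0.259
I,-0.709,1.216,-1.071,0.578,-0.031,1.26
K,-0.706,-0.356,1.057,-1.186,1.509,0.572
L,-0.93,0.902,-1.446,0.501,0.344,1.104
M,-0.358,0.145,-1.644,0.304,0.992,0.105
N,0.477,0.357,1.255,-0.333,0.077,-1.084
P,-0.446,-1.115,0.771,1.497,0.076,0.113
Q,0.462,0.471,0.492,-0.305,0.387,-1.06
R,-1.704,-0.33,1.633,-2.356,0.129,0.074
S,-0.416,-0.082,0.821,-0.148,-0.229,-0.864
T,0.024,0.108,0.766,0.244,-0.385,-0.583
V,-0.688,1.661,-0.642,0.574,-0.391,0.961
W,1.069,-2.007,-0.622,-0.628,-1.188,1.476
Y,1.653,-1.439,-0.008,-0.686,-2.097,1.085
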