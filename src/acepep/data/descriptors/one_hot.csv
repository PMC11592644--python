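residue,is_A,is_C,is_D,is_E,is_F,is_G,is_H,is_I,is_K,is_L,is_M,is_N,is_P,is_Q,is_R,is_S,is_T,is_V,is_W,is_Y
A,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
C,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
D,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
E,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
F,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
G,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
I,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
K,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0
L,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0
M,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0
N,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0
P,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0
Q,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0
R,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0
S,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0
T,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0
V,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0
W,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0
Y,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
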