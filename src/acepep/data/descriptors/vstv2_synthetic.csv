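residue,vstv1,vstv2
A,-1.691,1.85
C,0.27,-0.28
D,1.462,0.921
E,0.707,1.58
F,-0.039,-1.036
G,1.405,1.071
H,0.731,-0.326
I,-1.303,-0.518
K,-0.02,0.374
L,-1.384,0.262
M,-1.002,0.738
N,0.379,-0.384
P,1.697,1.037
Q,-0.417,-0.412
R,-1.065,-1.234
S,0.571,0.633
T,0.311,-0.253
V,-1.347,-0.529
W,-0.114,-1.589
Y,0.849,-1.904
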