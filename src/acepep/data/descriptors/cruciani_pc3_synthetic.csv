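residue,cruciani_pc1,cruciani_pc2,cruciani_pc3
A,1.264,-0.042,-1.131
C,-0.659,0.885,-0.21
D,-1.682,1.376,0.34
E,-1.182,0.944,0.692
F,0.456,-1.836,-0.037
G,-1.165,0.78,0.173
H,-0.604,-0.819,0.823
I,1.701,-0.332,-2.105
K,-0.014,-0.024,1.068
L,1.704,-0.454,-1.728
M,0.477,-0.071,-0.605
N,-0.586,1.156,0.642
P,-1.302,0.198,0.411
Q,0.108,0.834,0.786
R,0.45,-0.264,1.414
S,-0.791,0.887,0.406
T,-0.339,0.8,0.173
V,1.567,-0.114,-2.129
W,0.58,-2.31,0.566
Y,0.017,-1.594,0.45
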