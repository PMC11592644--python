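residue,isa_eci1,isa_eci2
A,-0.03,-0.436
C,-0.561,0.531
D,0.952,1.646
E,1.936,0.618
F,0.116,-0.94
G,0.787,1.686
H,0.578,-0.041
I,-1.596,-1.201
K,0.127,-0.61
L,-0.588,-1.23
M,0.127,-1.189
N,-0.616,1.247
P,2.037,1.18
Q,-0.69,0.21
R,-0.333,-1.058
S,0.403,1.105
T,-0.584,0.629
V,-2.164,-0.914
W,0.693,-1.182
Y,-0.595,-0.051
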