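residue,lin1,lin2,lin3
A,1.007,-0.732,0.185
C,-0.413,-0.223,-0.686
D,-0.232,-0.521,1.518
E,-0.961,-0.008,1.748
F,-1.718,-1.008,-0.327
G,1.347,-1.019,-1.522
H,0.552,0.394,-0.197
I,-0.576,-0.685,1.423
K,0.704,1.643,-0.573
L,-0.697,-0.653,0.956
M,-1.408,-0.026,0.983
N,1.138,0.745,-0.418
P,0.416,-0.851,-1.382
Q,0.355,1.289,0.238
R,1.886,3.085,-1.314
S,0.842,-0.084,-1.062
T,0.334,0.155,-0.264
V,-0.019,-0.742,1.445
W,-1.619,-0.301,-0.339
Y,-0.936,-0.459,-0.411
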