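residue,sneath1,sneath2,sneath3,sneath4
A,0.097,-0.969,-0.5,-0.351
C,1.369,0.197,1.248,0.049
D,-0.604,1.353,0.674,-2.068
E,-1.432,1.335,0.835,-1.831
F,-0.054,1.656,0.302,1.373
G,2.559,-0.048,-1.451,-1.022
H,-0.272,-0.069,-0.794,0.157
I,-0.711,-0.075,1.249,0.689
K,-0.451,-1.525,-0.81,-0.017
L,-0.74,-0.126,0.84,0.63
M,-0.75,-0.052,1.591,0.21
N,0.089,-0.453,-0.432,-0.681
P,1.651,0.121,-1.811,-0.643
Q,-0.608,-0.461,0.266,-0.294
R,-0.961,-2.636,-1.587,1.117
S,1.271,-0.193,-0.534,-0.689
T,0.839,-0.066,0.154,-0.349
V,-0.278,-0.34,1.244,0.479
W,-0.908,1.131,-0.845,1.822
Y,-0.107,1.219,0.363,1.42
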