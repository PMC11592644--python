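residue,ms_whim1,ms_whim2,ms_whim3
A,-0.874,1.667,-1.306
C,0.908,0.185,0.289
D,-0.991,-0.749,-0.935
E,-1.532,-0.463,-1.381
F,0.391,0.415,0.253
G,-1.201,0.009,-0.794
H,-0.882,-0.684,0.833
I,1.454,1.681,-0.508
K,-1.635,-0.922,0.445
L,1.099,1.703,-0.844
M,0.35,0.964,-0.898
N,0.02,-1.202,0.886
P,-0.624,-0.379,-0.815
Q,0.099,-0.885,0.489
R,-0.158,-1.54,2.816
S,-0.649,-0.299,-0.023
T,0.097,-0.285,-0.013
V,1.255,1.709,-0.498
W,1.31,-0.447,0.696
Y,1.563,-0.478,1.308
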