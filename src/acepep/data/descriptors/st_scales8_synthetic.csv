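residue,st_scales1,st_scales2,st_scales3,st_scales4,st_scales5,st_scales6,st_scales7,st_scales8
A,0.192,1.188,-0.293,-0.32,-0.446,1.967,-1.118,0.872
C,-0.675,1.199,-1.06,-0.485,0.032,-0.203,1.071,-0.57
D,2.504,0.481,1.577,-1.332,-1.508,-0.572,-1.516,-1.704
E,2.438,-0.011,2.294,-0.419,-1.573,0.308,-2.5,-1.209
F,-0.55,0.115,0.596,0.363,1.641,-0.898,-1.098,0.701
G,-0.43,1.068,-1.29,-1.958,-0.705,0.163,0.209,0.862
H,-0.083,-1.07,0.829,0.452,-0.187,-0.832,-0.293,0.677
I,0.107,0.697,-1.124,-0.107,1.15,1.11,0.625,-0.891
K,-0.767,-2.19,-0.348,0.672,-0.512,0.35,0.709,2.843
L,0.106,0.62,-0.458,0.037,0.925,1.608,0.293,-0.459
M,0.441,0.223,0.099,0.577,0.297,1.36,-0.377,0.25
N,0.095,-0.13,0.123,-0.201,-0.94,-1.043,0.698,-0.74
P,-0.191,0.149,-0.076,-1.482,-0.223,0.433,0.837,0.744
Q,0.141,-0.528,-0.045,0.877,-0.669,-0.55,-0.219,-0.755
R,-2.346,-2.433,0.144,2.449,-0.543,-0.48,2.187,0.927
S,-0.374,0.639,-0.379,-0.847,-0.831,-0.068,0.276,0.233
T,-0.215,0.37,-1.072,-0.347,-0.266,-0.343,0.246,-0.368
V,0.152,1.012,-1.677,-0.206,0.926,0.908,0.389,-0.827
W,-0.453,-0.942,1.433,1.504,1.945,-1.154,-0.531,-0.034
Y,-0.093,-0.458,0.728,0.774,1.488,-2.065,0.11,-0.551
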