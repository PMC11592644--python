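residue,zimmerman1,zimmerman2,zimmerman3,zimmerman4,zimmerman5,zimmerman6
A,1.194,0.601,-1.46,2.111,0.333,-0.785
C,-1.368,0.344,0.351,0.707,0.54,0.638
D,1.794,-1.921,0.946,0.166,-0.194,-1.744
E,2.267,-2.797,0.216,0.312,-1.272,-1.895
F,0.078,0.698,0.349,0.141,-1.591,1.665
G,0.483,1.32,0.37,0.595,-0.294,-0.197
H,0.592,-0.082,0.706,-0.887,-1.307,-0.211
I,-1.6,0.863,-1.611,0.751,1.649,0.657
K,0.076,0.42,-0.701,-1.61,-1.299,-0.849
L,-1.222,0.641,-1.795,0.985,1.063,0.468
M,-0.59,-0.548,-1.486,0.91,-0.356,0.076
N,0.457,-0.445,1.287,-0.661,1.128,-0.808
P,-0.184,0.957,-0.113,-0.282,-0.798,0.142
Q,0.563,-1.346,0.733,-0.613,0.899,-0.595
R,-0.733,-0.243,0.412,-2.251,0.026,-0.278
S,0.348,0.276,0.561,0.362,-0.043,-0.435
T,-0.12,-0.042,0.457,-0.051,0.683,0.039
V,-1.212,0.949,-1.354,1.07,1.945,0.515
W,-0.022,-0.063,0.556,-0.997,-0.982,1.998
Y,-0.803,0.416,1.577,-0.757,-0.131,1.6
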