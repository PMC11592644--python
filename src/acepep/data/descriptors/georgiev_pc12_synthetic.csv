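residue,georgiev_pc1,georgiev_pc2,georgiev_pc3,georgiev_pc4,georgiev_pc5,georgiev_pc6,georgiev_pc7,georgiev_pc8,georgiev_pc9,georgiev_pc10,georgiev_pc11,georgiev_pc12
A,1.297,1.355,-0.32,0.726,-0.871,0.351,1.23,-0.645,1.266,0.525,-1.708,1.188
C,-0.167,-0.869,-0.376,1.21,-0.001,-0.207,-1.308,-0.103,-0.483,-0.164,-0.7,0.628
D,-0.709,-1.826,2.391,-0.067,1.813,1.599,1.727,0.039,0.25,-2.164,1.508,1.345
E,-0.967,-0.689,2.505,-0.879,1.127,2.316,2.37,-0.323,-0.034,-0.946,1.526,1.359
F,1.041,1.021,-0.077,-0.549,0.498,-0.289,-1.088,-1.273,-2.228,1.339,0.794,-0.569
G,0.099,-0.356,-0.367,1.725,0.757,-1.519,0.313,0.639,0.923,-0.767,0.114,1.502
H,-0.427,0.387,0.701,-0.959,0.661,-0.686,0.354,0.594,0.139,0.249,0.622,-0.579
I,1.488,0.653,-1.084,0.954,-1.479,0.747,-0.944,-1.654,0.089,0.308,-0.72,-0.579
K,-1.302,2.101,-1.169,-1.329,-0.563,-1.245,0.646,0.931,1.287,0.229,0.235,-0.773
L,1.3,0.943,-1.155,0.763,-1.203,1.002,-0.423,-1.445,0.201,0.962,-0.726,-0.313
M,0.299,1.169,-0.444,-0.205,-0.917,1.296,-0.134,-1.142,-0.125,1.033,-0.026,0.263
N,-0.96,-1.701,0.609,-0.08,0.695,-0.311,0.358,1.325,0.45,-1.59,-0.558,0.031
P,-0.33,-0.493,-0.896,1.05,1.184,-0.9,0.246,0.592,0.809,0.294,1.174,0.671
Q,-0.89,-0.778,0.782,-0.807,-0.571,0.344,0.391,0.945,-0.138,-0.965,-0.387,-0.163
R,-2.021,0.207,-0.697,-1.689,-1.291,-1.539,-0.097,2.037,0.974,1.105,-1.933,-2.05
S,-0.484,-0.643,0.079,0.806,0.567,-0.648,0.311,0.693,0.486,-0.563,-0.528,0.948
T,-0.239,-0.639,0.066,0.522,-0.321,-0.411,-0.304,0.399,-0.066,-0.892,-0.115,0.398
V,1.695,0.574,-0.783,1.109,-1.664,0.418,-0.926,-1.456,0.279,-0.233,-1.002,-0.236
W,0.62,0.074,-0.143,-1.55,0.392,0.002,-1.078,-0.372,-2.252,1.858,1.353,-1.639
Y,0.656,-0.492,0.378,-0.751,1.187,-0.322,-1.644,0.219,-1.826,0.382,1.075,-1.431
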