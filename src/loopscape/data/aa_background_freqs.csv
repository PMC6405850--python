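# Background amino-acid frequencies (database composition, normalised).
aa,freq
A,0.078078
C,0.019019
D,0.054054
E,0.063063
F,0.039039
G,0.074074
H,0.022022
I,0.051051
K,0.057057
L,0.091091
M,0.022022
N,0.045045
P,0.052052
Q,0.043043
R,0.051051
S,0.071071
T,0.058058
V,0.064064
W,0.013013
Y,0.032032
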