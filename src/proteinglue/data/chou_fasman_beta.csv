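# Chou-Fasman beta-sheet conformational propensity P_beta
# (Chou & Fasman, Biochemistry 13:222-245, 1974; Adv. Enzymol. 47:45-148, 1978)
residue,value
A,0.83
R,0.93
N,0.89
D,0.54
C,1.19
Q,1.10
E,0.37
G,0.75
H,0.87
I,1.60
L,1.30
K,0.74
M,1.05
F,1.38
P,0.55
S,0.75
T,1.19
W,1.37
Y,1.47
V,1.70
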