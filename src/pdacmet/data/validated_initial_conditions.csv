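metabolite,IC1_mM,IC2_mM
GLC,14.0,3.1
ATP,7.7,9.9
G6P,1.2,1.8
ADP,1.9,1.0
F6P,0.21,0.028
FBP,0.1,0.38
DHAP,0.88,0.77
G3P,0.57,0.044
NAD,0.31,0.81
13BPG,0.0067,0.014
3PG,0.34,0.099
2PG,0.049,0.045
PEP,0.054,0.21
PYR,8.1,4.4
LAC,19.0,63.0
AMP,0.25,1.3
6PG,0.0045,0.0094
Ru5P,0.027,0.076
Xyl5P,0.013,0.013
R5P,0.014,0.006
E4P,0.18,0.052
S7P,0.057,0.071
NADP,0.38,0.072
GSH,2.1,3.1
mPYR,7.9,6.9
mAcCoA,0.12,0.1
mCIT,0.098,0.5
mICIT,0.017,0.0249
mAKG,0.02,0.0157
mSCoA,0.72,1.5
mSUC,2.5,1.8
mFUM,0.16,0.16
mMAL,1.2,2.2
mOAA,1.9,1.7
mASP,4.3,3.2
mGLU,2.0,0.3
ASP,7.0,6.7
GLU,2.8,3.2
OAA,1.2,1.2
MAL,1.9,2.1
AKG,0.0061,0.021
CIT,0.51,0.17
GLN,4.3,5.5
NADH,0.061,0.0097
NADPH,0.0056,0.033
GSSG,0.32,0.91
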