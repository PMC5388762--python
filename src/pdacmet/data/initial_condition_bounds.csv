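metabolite,lower_mM,upper_mM
GLC,2.5,14.0
ATP,0.014,14.0
G6P,0.0061,2.1
ADP,0.0026,4.8
F6P,0.00034,0.84
FBP,0.0085,0.45
DHAP,0.0029,1.2
G3P,0.0008,1.2
NAD,0.018,2.2
13BPG,0.0008,0.12
3PG,0.0084,0.49
2PG,0.0056,0.06
PEP,0.0018,0.38
PYR,0.012,14.0
LAC,0.08,73.0
AMP,3.6e-05,3.4
6PG,0.0032,0.011
Ru5P,0.0094,0.078
Xyl5P,8e-05,0.019
R5P,0.003,0.022
E4P,8e-05,0.27
S7P,0.0065,0.081
NADP,0.0037,0.44
GSH,0.099,3.4
mPYR,0.012,14.0
mAcCoA,0.00017,0.17
mCIT,0.0064,1.2
mICIT,0.01,0.056
mAKG,0.0058,0.023
mSCoA,0.16,3.0
mSUC,0.17,2.8
mFUM,0.017,0.22
mMAL,0.096,2.4
mOAA,0.096,2.4
mASP,0.23,7.8
mGLU,0.0056,6.6
ASP,0.23,7.8
GLU,0.0056,6.6
OAA,0.096,2.4
MAL,0.096,2.4
AKG,0.0057,0.023
CIT,0.0064,1.2
GLN,0.16,5.6
NADH,0.0008,0.1
NADPH,0.00096,0.069
GSSG,0.1,1.1
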