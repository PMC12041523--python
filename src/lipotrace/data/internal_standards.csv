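# Class-matched internal standards: one spiked, non-endogenous lipid per class
# with its known amount (nmol per sample pellet).  Two classes were spiked with
# a second standard (Cer(d18:1/25:0) 0.130 nmol; S1P(d17:0) 0.124 nmol); the
# rows below keep one standard per class, which the normalization contract
# requires.  Override with your own CSV to change the choice.
class,standard,nmol
BMP,BMP(14:0)2,0.2
C1P,C1P(d18:1/12:0),0.127
CE,CE(16:0)(d7),2
Cer,Cer(d18:1/12:0),0.118
CL,CL(14:0)4,0.1
DAG,DAG(14:0)2,0.5
GlcCer,GlcCer(d18:1/12:0),0.126
LacCer,LacCer(d18:1/12:0),0.129
LPA,LPA(14:0),0.1
LPC,LPC(14:0),0.5
LPE,LPE(14:0),0.1
LPG,LPG(14:0),0.02
PA,PA(14:0)2,0.5
PC,PC(14:0)2,2
PE,PE(14:0)2,0.5
PG,PG(14:0)2,0.1
PI,PI(8:0)2,0.5
PS,PS(14:0)2,5
S1P,S1P(d17:1),0.125
SM,SM(d18:1/12:0),2.129
SPH,SPH(d17:0),0.125
TAG,TAG(14:0)2,0.5
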