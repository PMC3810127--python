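protein,protein_ascii,is_phospho,p_mean,dir_mean,p_s1,dir_s1,p_s2,dir_s2,p_s3,dir_s3
4E-BP1,4E-BP1,0,0.000,up,0.001,up,0.002,up,0.001,up
EGFR,EGFR,0,0.000,up,0.005,up,0.004,up,0.001,up
HER2,HER2,0,0.000,up,0.000,up,0.002,up,0.000,up
pB-Raf,pB-Raf,1,0.000,down,0.026,up,0.000,up,0.001,up
pPTEN,pPTEN,1,0.000,up,0.008,up,0.004,up,0.002,up
pS6RP,pS6RP,1,0.003,up,0.005,up,0.002,up,0.000,up
pVEGFR,pVEGFR,1,0.006,down,0.003,up,0.009,up,0.004,up
VEGF,VEGF,0,0.000,up,0.000,up,0.000,up,0.004,up
VEGFR,VEGFR,0,0.001,down,0.002,down,0.003,down,0.000,down
VHL,VHL,0,0.006,up,0.000,up,0.000,up,0.000,up
pHER2,pHER2,1,,,0.001,up,0.000,up,0.000,up
PI3K,PI3K,0,,,0.026,up,0.004,down,0.005,up
AKT,AKT,0,0.030,up,,,0.006,up,,
pAKT,pAKT,1,0.018,down,0.000,,,,,
Angiopoietin2,Angiopoietin2,0,0.000,up,,,,,,
B-Raf,B-Raf,0,0.000,down,,,,,0.042,up
p1068EGFR,p1068EGFR,1,0.000,down,,,,,0.049,up
p1148EGFR,p1148EGFR,1,0.000,up,,,,,,
FAK,FAK,0,0.000,up,,,,,,
GSK3β,GSK3b,0,,,,,,,,
pGSK3β,pGSK3b,1,0.000,up,0.036,up,0.021,up,,
Hif-1α,Hif-1a,0,0.000,down,,,,,,
JNK/SAPK,JNK/SAPK,0,0.000,up,,,,,0.021,up
mTOR,mTOR,0,0.000,up,,,,,,
pmTOR,pmTOR,1,0.000,down,,,,,,
p4E-BP1,p4E-BP1,1,,,,,,,,
p38 MAPK,p38 MAPK,0,0.000,up,,,,,0.003,up
pp38 MAPK,pp38 MAPK,1,,,,,,,,
ERK,ERK,0,,,,,,,,
pERK,pERK,1,,,,,,,,
pPRAS40,pPRAS40,1,0.000,down,,,,,,
PTEN,PTEN,0,0.010,up,,,,,,
pPDGFR,pPDGFR,1,0.003,down,0.026,up,,,0.018,up
PDGF,PDGF,0,0.042,down,,,,,,
S6RP,S6RP,0,0.000,up,,,,,,
PRAS40,PRAS40,0,0.002,up,,,,,,
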