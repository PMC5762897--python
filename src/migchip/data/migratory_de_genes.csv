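gene,direction,log2fc_sum159,log2fc_mdamb231
GHRL,up,3.45,2.87
SERPINE1,up,4.75,2.35
PER1,up,1.91,1.58
RGS2,up,2.27,1.53
SNAI2,up,1.25,2.17
PMEPA1,up,2.81,1.19
THBS1,up,1.50,1.12
SLC7A2,up,2.63,1.10
FSTL3,up,1.43,1.10
HSF2BP,up,3.13,1.08
PHLDB1,up,3.19,1.06
UBAP2,up,1.43,1.03
FKBP5,up,3.13,1.00
COL4A1,up,2.91,1.00
DMBT1,up,0.98,4.30
NEIL2,up,1.14,0.95
NFIA,up,0.92,1.09
KRT7,up,0.90,0.98
COL4A2,up,2.31,0.86
TUBA4A,up,0.85,1.16
PISD,down,-3.58,-2.83
CXCL8,down,-2.58,-5.68
CXCL2,down,-2.51,-2.57
GDF15,down,-2.39,-3.49
CELSR3,down,-2.12,-3.45
KYNU,down,-2.13,-2.11
CXCL3,down,-2.10,-2.28
ISG20,down,-3.13,-1.92
ZMIZ1AS1,down,-1.87,-2.47
PTGS2,down,-1.84,-4.86
F2RL2,down,-1.92,-1.77
FAIM3,down,-2.91,-1.64
CEMIP,down,-1.63,-1.76
NR4A2,down,-1.63,-1.65
RNF170,down,-1.60,-6.17
MX2,down,-1.55,-1.86
CD24,down,-1.55,-1.57
CSF1,down,-1.46,-2.33
CA11,down,-1.60,-1.45
SYT17,down,-1.67,-1.43
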