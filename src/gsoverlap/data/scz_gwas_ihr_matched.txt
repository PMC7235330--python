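# Schizophrenia GWAS genes matching well-recognized brain
# ischemia-hypoxia response genes (25 symbols).
AKT3
ATP2A2
BNIP3L
CACNA1C
CACNB2
CLU
FGFR1
FURIN
HSPA9
HSPD1
HSPE1
INA
MDK
MEF2C
NCAN
NGEF
NRGN
OPCML
PTK2B
RANGAP1
RELA
SERPING1
SF3B1
SREBF1
SRPK2
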