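# Schizophrenia GWAS genes annotated for a role of the
# hypoxia-inducible factors (33 symbols).
ALDOA
ALPK3
BNIP3L
BTG1
CDK2AP1
CPEB1
CPT1C
CREB3L1
CUL3
EP300
ESRP2
FGFR1
FURIN
GPR135
HSPA9
KAT5
KDM4A
KMT5A
LRP1
LSM1
MAD1L1
NEK1
NMB
OGFOD2
OTUD7B
PGM3
PPP2R2A
PRMT1
RALGAPA2
RPTOR
SF3B1
TCF4
ZEB2
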