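ligand,receptor,pathway
PDL1,PD1,PD1-PDL1
PDL2,PD1,PD1-PDL2
CD80,CTLA4,CTLA4-CD80
CD86,CTLA4,CTLA4-CD86
CD80,CD28,CD28-CD80
CD86,CD28,CD28-CD86
ICOSL,ICOS,ICOS-ICOSL
OX40L,OX40,OX40-OX40L
CD137L,CD137,CD137-CD137L
HVEM,BTLA,BTLA-HVEM
PVR,TIGIT,TIGIT-PVR
GAL9,TIM3,TIM3-GAL9
FASL,FAS,FAS-FASL
CD40,CD40L,CD40L-CD40
HLA-DR,LAG3,LAG3-HLADR
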