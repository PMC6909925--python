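id,label,kind,aliases
Fibroblast,fibroblast identity,phenotype,
Doxycycline,doxycycline,compound,Dox
MYOD1_exo,exogenous MyoD1 transgene,gene,MYOD1-exogenous
OCT4_exo,exogenous OCT3/4 reprogramming factor,gene,OCT3/4-exogenous
SOX2_exo,exogenous SOX2 reprogramming factor,gene,SOX2-exogenous
KLF4,KLF4 reprogramming factor,gene,
cMYC,cMYC reprogramming factor,gene,c-MYC
pluripotency_program,pluripotency transcriptional program,phenotype,
NANOG,NANOG,protein,
OCT4_endo,endogenous OCT3/4,gene,OCT3/4;OCT3/4-endogenous
SOX2_endo,endogenous SOX2,gene,SOX2;SOX2-endogenous
GDF3,growth and differentiation factor 3,gene,
REX1,reduced expression 1,gene,ZFP42
FGF4,fibroblast growth factor 4,gene,
DPPA5,embryonic cell-specific gene 1,gene,ESG1;ESG1/DPPA5
DPPA2,developmental pluripotency-associated 2,gene,
DPPA4,developmental pluripotency-associated 4,gene,
hTERT,telomerase reverse transcriptase,gene,TERT
SALL4,SALL4,gene,
E_CADHERIN,E-cadherin,protein,E-CADHERIN;CDH1
SSEA34,stage-specific embryonic antigen 3/4,protein,SSEA-3/4;SSEA3;SSEA4
TRA_1_81,tumor-related antigen 1-81,protein,TRA-1-81
ALP,alkaline phosphatase,protein,
myogenic_program,myogenic transcriptional program,phenotype,
MyoD1_endo,endogenous MyoD1,gene,MyoD1-endogenous
CKM,muscle creatine kinase,gene,
MyHC,myosin heavy chain,protein,MYH
Myogenin,myogenin,gene,MYOG
Pax7,Pax7,gene,
GAA,acid alpha-glucosidase,gene,
lysosomal_glycogen,lysosomal glycogen burden,phenotype,
LAMP2,lysosome-associated membrane protein 2,protein,
glucose_deprivation,glucose deprivation,phenotype,
mTORC1_p,phospho-mTORC1 activity,protein,mTORC1-p
p70S6K_p,phospho-p70S6K,protein,p70S6K-p
p4EBP1_p,phospho-4EBP1,protein,p4EBP1-p
VDCC,voltage-dependent calcium channel activity,protein,L-type calcium channel
intracellular_calcium,intracellular calcium concentration,phenotype,
lysosomal_calcium,lysosomal calcium concentration,phenotype,
calpain,calpain activity,protein,calpains
mitochondrial_dysfunction,mitochondrial dysfunction,phenotype,
impaired_energy_metabolism,impaired energy metabolism,phenotype,
ATP,ATP level,compound,
ADP,ADP level,compound,
ROS,reactive oxygen species,compound,
CytC,cytochrome c,protein,Cytochrome C
AIF,apoptosis-inducing factor,protein,
Caspase3,caspase 3,protein,Caspase 3
apoptosis,apoptosis,phenotype,
cell_death,cell death,phenotype,
DNM1L,dynamin-1-like shaping protein,protein,
MFN2,mitofusin 2,protein,
autophagy,autophagy,phenotype,
mitophagy,mitophagy,phenotype,
LC3,LC3/LC3-II autophagosome marker,protein,LC3/LC3-II;LC3-II;LCII
p62,p62 (SQSTM1),protein,SQSTM1
Pink2,Pink2,protein,PINK2
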