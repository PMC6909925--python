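source,target,weight,provenance
OCT4_exo,pluripotency_program,0.5,anchored: key transcription factors turned on to induce pluripotency
SOX2_exo,pluripotency_program,0.5,anchored: key transcription factors turned on to induce pluripotency
KLF4,pluripotency_program,0.5,anchored: key transcription factors turned on to induce pluripotency
cMYC,pluripotency_program,0.5,anchored: key transcription factors turned on to induce pluripotency
pluripotency_program,NANOG,1.0,anchored: NANOG protein expressed in aiPSC
NANOG,pluripotency_program,1.0,curated: closure edge
OCT4_endo,pluripotency_program,0.3,curated: closure edge
SOX2_endo,pluripotency_program,0.3,curated: closure edge
pluripotency_program,OCT4_endo,1.0,anchored: undifferentiated ESC markers upregulated/expressed
pluripotency_program,SOX2_endo,1.0,anchored: undifferentiated ESC markers upregulated/expressed
pluripotency_program,GDF3,1.0,anchored: undifferentiated ESC markers upregulated/expressed
pluripotency_program,REX1,1.0,anchored: undifferentiated ESC markers upregulated/expressed
pluripotency_program,FGF4,1.0,anchored: undifferentiated ESC markers upregulated/expressed
pluripotency_program,DPPA5,1.0,anchored: undifferentiated ESC markers upregulated/expressed
pluripotency_program,DPPA2,1.0,anchored: undifferentiated ESC markers upregulated/expressed
pluripotency_program,DPPA4,1.0,anchored: undifferentiated ESC markers upregulated/expressed
pluripotency_program,hTERT,1.0,anchored: undifferentiated ESC markers upregulated/expressed
pluripotency_program,SALL4,1.0,anchored: similar levels in iPSC and hESC by western blotting
pluripotency_program,E_CADHERIN,1.0,anchored: similar levels in iPSC and hESC by western blotting
pluripotency_program,SSEA34,1.0,anchored: human ESC specific surface antigens expressed
pluripotency_program,TRA_1_81,1.0,anchored: human ESC specific surface antigens expressed
pluripotency_program,ALP,1.0,anchored: alkaline phosphatase expressed in aiPSC
pluripotency_program,myogenic_program,-1.0,curated: closure edge
myogenic_program,pluripotency_program,-1.0,anchored: loss of pluripotency in differentiated aiSkMC
pluripotency_program,MyoD1_endo,-1.0,anchored: transient MyoD1 expression without sustained endogenous expression
NANOG,MyoD1_endo,-0.5,curated: closure edge
MYOD1_exo,MyoD1_endo,1.0,anchored: direct conversion by overexpression of MYOD1
Doxycycline,MyoD1_endo,0.2,anchored: in the presence of Doxycycline
MyoD1_endo,myogenic_program,1.0,anchored: MyoD1 master regulator of skeletal muscle differentiation
myogenic_program,MyoD1_endo,0.5,curated: closure edge
myogenic_program,CKM,1.0,anchored: expressed/upregulated factors included MyoD1 CKM MyHC and Myogenin
myogenic_program,MyHC,1.0,anchored: expressed/upregulated factors included MyoD1 CKM MyHC and Myogenin
myogenic_program,Myogenin,1.0,anchored: expressed/upregulated factors included MyoD1 CKM MyHC and Myogenin
myogenic_program,Pax7,-1.0,anchored: while Pax7 was down regulated
Myogenin,myogenic_program,0.3,curated: closure edge
Fibroblast,GAA,0.15,curated: closure edge
GAA,lysosomal_glycogen,-1.0,anchored: conversion of glycogen to glucose
GAA,glucose_deprivation,-0.8,curated: closure edge
lysosomal_glycogen,LAMP2,0.8,anchored: lysosomal glycogen and LAMP2 increased/upregulated
lysosomal_glycogen,mTORC1_p,-1.0,anchored: mTORC1 suppressed in association with lysosomal glycogen accumulation
Doxycycline,mTORC1_p,0.4,anchored: tetracycline-type drugs affect PI3K-AKT-mTOR pathways
mTORC1_p,p70S6K_p,1.0,anchored: phosphorylation of downstream targets p70S6K and p4EBP1
mTORC1_p,p4EBP1_p,1.0,anchored: phosphorylation of downstream targets p70S6K and p4EBP1
mTORC1_p,autophagy,-0.5,curated: closure edge
lysosomal_glycogen,autophagy,0.8,curated: closure edge
lysosomal_glycogen,VDCC,0.5,curated: closure edge
calpain,VDCC,0.5,curated: closure edge
VDCC,intracellular_calcium,1.0,anchored: calcium influx via calcium channels of the VDCC class
intracellular_calcium,calpain,1.0,curated: closure edge
calpain,mitochondrial_dysfunction,0.8,curated: closure edge
glucose_deprivation,mitochondrial_dysfunction,0.3,curated: closure edge
glucose_deprivation,impaired_energy_metabolism,0.5,curated: closure edge
mitochondrial_dysfunction,impaired_energy_metabolism,0.7,anchored: metabolism impaired as a subnetwork of mitochondrial dysfunction
mitochondrial_dysfunction,ROS,1.0,anchored: associated with increased Cytochrome C AIF and ROS
mitochondrial_dysfunction,CytC,1.0,anchored: associated with increased Cytochrome C AIF and ROS
mitochondrial_dysfunction,AIF,1.0,anchored: associated with increased Cytochrome C AIF and ROS
mitochondrial_dysfunction,ADP,0.8,anchored: ADP levels markedly elevated
mitochondrial_dysfunction,ATP,-0.8,anchored: reduction in ATP levels
mitochondrial_dysfunction,Caspase3,0.8,anchored: Caspase 3 levels also elevated
Caspase3,apoptosis,0.8,anchored: evidence of increased apoptosis
apoptosis,cell_death,0.7,curated: closure edge
calpain,cell_death,0.5,curated: closure edge
mitochondrial_dysfunction,DNM1L,0.8,anchored: DNM1L and MFN2 expressed/overexpressed
mitochondrial_dysfunction,MFN2,0.8,anchored: DNM1L and MFN2 expressed/overexpressed
mitochondrial_dysfunction,mitophagy,0.8,curated: closure edge
autophagy,LC3,1.0,anchored: LC3/LCII autophagosome markers significantly elevated
autophagy,p62,1.0,anchored: p62(SQSTM1) receptor for LC3 elevated
mitophagy,Pink2,1.0,anchored: Pink2 significantly increased
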