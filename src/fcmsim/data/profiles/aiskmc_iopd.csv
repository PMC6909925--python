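concept,expected,provenance
GAA,down,GAA markedly decreased under glucose deprivation
lysosomal_glycogen,up,hallmark accumulation of lysosomal glycogen
LAMP2,up,LAMP2 increased/upregulated
glucose_deprivation,up,loss of glycogen-to-glucose conversion
mTORC1_p,down,mTORC1 phosphoactivation significantly suppressed
p70S6K_p,down,downstream target phosphorylation suppressed
p4EBP1_p,down,downstream target phosphorylation suppressed
mitochondrial_dysfunction,up,mitochondrial dysfunction significantly increased
impaired_energy_metabolism,up,energy metabolism impaired in disease myocytes
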