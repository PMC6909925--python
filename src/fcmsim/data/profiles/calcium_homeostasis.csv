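concept,expected,provenance
intracellular_calcium,up,marked increase in intracellular calcium concentration
VDCC,up,increased calcium influx via VDCC-class channels
calpain,up,calcium-activated protease elevated in disease simulations
lysosomal_calcium,unchanged,lysosomal calcium concentration not different from WT
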