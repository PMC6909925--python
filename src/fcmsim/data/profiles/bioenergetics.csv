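concept,expected,provenance
ADP,up,ADP levels markedly elevated versus WT
ATP,down,reduced ATP generation versus WT
impaired_energy_metabolism,up,mitochondrial metabolism impaired
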