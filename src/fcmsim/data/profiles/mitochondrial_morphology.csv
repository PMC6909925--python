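concept,expected,provenance
DNM1L,up,shaping protein expressed/overexpressed versus WT
MFN2,up,shaping protein expressed/overexpressed versus WT
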