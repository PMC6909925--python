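concept,expected,provenance
LC3,up,LC3/LCII autophagosome markers significantly elevated
p62,up,p62(SQSTM1) receptor for LC3 elevated
Pink2,up,Pink2 significantly increased
autophagy,up,autophagy active in disease muscle cells
mitophagy,up,mitophagy active in disease muscle cells
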