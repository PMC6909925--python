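concept,expected,provenance
OCT4_endo,up,ESC signature factor expressed in iPSC
SOX2_endo,up,ESC signature factor expressed in iPSC
NANOG,up,ESC signature factor expressed in iPSC
GDF3,up,ESC signature factor expressed in iPSC
REX1,up,ESC signature factor expressed in iPSC
FGF4,up,ESC signature factor expressed in iPSC
DPPA5,up,ESC signature factor expressed in iPSC
DPPA2,up,ESC signature factor expressed in iPSC
DPPA4,up,ESC signature factor expressed in iPSC
hTERT,up,ESC signature factor expressed in iPSC
SALL4,up,similar levels in iPSC and hESC by western blotting
E_CADHERIN,up,similar levels in iPSC and hESC by western blotting
SSEA34,up,ESC specific surface antigen
TRA_1_81,up,ESC specific surface antigen
ALP,up,alkaline phosphatase expressed
GAA,up,expressed at levels just above normal/baseline in WT aiPSC
MyoD1_endo,down,transient MyoD1 expression without sustained endogenous expression
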