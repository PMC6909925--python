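concept,expected,provenance
NANOG,up,pluripotency marker retained in IOPD aiPSC
OCT4_endo,up,pluripotency marker retained in IOPD aiPSC
SSEA34,up,pluripotency marker retained in IOPD aiPSC
TRA_1_81,up,pluripotency marker retained in IOPD aiPSC
lysosomal_glycogen,up,modest increase in lysosomal glycogen
GAA,down,GAA gene locked off
MyoD1_endo,down,MyoD1-transfected aiPSC retained pluripotency without sustained MyoD1
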