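concept,expected,provenance
MyoD1_endo,up,mature skeletal muscle marker expressed
CKM,up,mature skeletal muscle marker expressed
MyHC,up,mature skeletal muscle marker expressed
Myogenin,up,mature skeletal muscle marker expressed
Pax7,down,Pax7 down regulated on differentiation
NANOG,down,loss of pluripotency in differentiated cells
OCT4_endo,down,loss of pluripotency in differentiated cells
SSEA34,down,loss of pluripotency in differentiated cells
TRA_1_81,down,loss of pluripotency in differentiated cells
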