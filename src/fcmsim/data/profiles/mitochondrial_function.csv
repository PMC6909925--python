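concept,expected,provenance
CytC,up,mitochondrial dysfunction associated with increased Cytochrome C
AIF,up,mitochondrial dysfunction associated with increased AIF
ROS,up,mitochondrial dysfunction associated with increased ROS
Caspase3,up,Caspase 3 levels elevated
apoptosis,up,evidence of increased apoptosis
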