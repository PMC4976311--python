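variant
A636G
T4363C
T10454C
A15924G
G600A
T620C
C4340T
G15900A
C12150T
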