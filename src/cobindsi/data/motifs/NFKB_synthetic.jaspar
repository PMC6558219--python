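>NFKB_SYN synthetic NFkB (p65-p50) consensus-style count matrix
A [  1  1  1 97  1  1  1  1  1  1  1 25 ]
C [  1  1  1  1 97  1  1  1 97 97 97 25 ]
G [ 97 97 97  1  1  1  1  1  1  1  1 25 ]
T [  1  1  1  1  1 97 97 97  1  1  1 25 ]
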