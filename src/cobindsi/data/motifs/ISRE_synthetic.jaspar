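>ISRE_SYN synthetic ISRE (ISGF3) consensus-style count matrix
A [ 97  1  1  1  1  1  1  1  1  1  1 25 ]
C [  1  1  1  1  1 97  1  1  1  1 97 25 ]
G [  1 97  1  1  1  1 97  1  1  1  1 25 ]
T [  1  1 97 97 97  1  1 97 97 97  1 25 ]
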