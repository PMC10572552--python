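genotype,low,average,high
AA,219,212,110
AG,42,21,9
GG,1,0,0
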