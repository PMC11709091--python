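# Abundant blood-component proteins: albumin, hemoglobin chains, red
# blood cell membrane/cytoskeleton proteins, platelet proteins.
ALB
HBA1
HBB
HBD
ANK1
SLC4A1
SPTA1
SPTB
CA1
GP1BA
ITGA2B
ITGB3
PF4
THBS1
SELP
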