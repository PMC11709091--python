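# Complement system components, typically enriched in the
# protein (PROT) SEC fraction relative to EVs.
C1QA
C1QB
C1QC
C1R
C1S
C2
C3
C4A
C4B
C5
C6
C7
C8A
C8B
C8G
C9
CFB
CFD
CFH
CFI
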