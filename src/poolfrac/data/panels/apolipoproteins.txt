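# Apolipoproteins: protein components of plasma lipoproteins
# (HDL/LDL/VLDL), classic co-isolates of plasma EVs in SEC.
APOA1
APOA2
APOA4
APOA5
APOB
APOC2
APOC3
APOC4
APOD
APOE
APOF
APOH
APOL1
APOM
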