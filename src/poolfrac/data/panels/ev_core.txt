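# Canonical EV marker panel: tetraspanins and cytosolic/ESCRT proteins
# used to judge EV enrichment of a fraction (MISEV-style core markers).
# Nomenclature varies between quantification outputs, so common aliases
# are listed as separate identifiers (no automatic alias resolution):
# SDCBP = Syntenin = Syntennin, PDCD6IP = ALIX.
CD9
CD63
CD81
FLOT1
TSG101
SDCBP
Syntenin
PDCD6IP
ALIX
ANXA11
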