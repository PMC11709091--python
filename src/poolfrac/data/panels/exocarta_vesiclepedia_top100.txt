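# Proteins of the EV / PROT fractions matched to the top-100 most
# commonly reported EV proteins of both the Exocarta and Vesiclepedia
# databases (n = 72).  Identifiers as printed in the source tables;
# "Syntennin" = SDCBP, "ALIX" = PDCD6IP (no automatic alias resolution).
#
# detected in EVs and PROT:
A2M
ACTB
ALDOA
ANXA2
ANXA5
CFL1
CLTC
EEF2
ENO1
FLNA
GAPDH
GSN
HSP90AA1
HSP90AB1
HSPA5
HSPA8
ITGB1
LDHA
LDHB
LGALS3BP
PFN1
PGK1
PKM
PPIA
PRDX1
PRDX2
RAN
SLC3A2
TFRC
TPI1
YWHAB
# detected only in EVs:
CD63
CD81
CD9
ALIX
Syntennin
FLOT1
ACLY
ACTN4
AHCY
ANXA1
ANXA11
ANXA6
ATP1A1
BSG
CCT2
CCT3
CCT5
CDC42
CLIC1
EZR
GDI2
GNAI2
GNAS
GNB1
GNB2
KPNB1
MFGE8
MSN
RAB5C
RAB7A
RAC1
RAP1B
RHOA
TCP1
TSG101
UBA1
VCP
YWHAE
YWHAG
YWHAQ
YWHAZ
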