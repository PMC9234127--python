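# Curated list of 73 commonly used human reference (housekeeping) genes,
# assembled from widely cited reference-gene selection studies across
# tissues, blood cells and cancer panels. One symbol per line; replaceable
# via the known_list_path config key.
ACTB
GAPDH
B2M
YWHAZ
GNAS
OAZ1
PTMA
HPRT1
TBP
GUSB
PPIA
PGK1
RPL13A
RPLP0
SDHA
TFRC
UBC
HMBS
ACTG1
RPS18
EEF1A1
TUBB
HSP90AB1
POLR2A
PPIB
RPL32
RPS29
ALAS1
CYC1
EIF4A2
ATP5F1B
MRPL19
PSMC4
PUM1
RPL30
RPS17
RPS13
TUBA1A
UBB
VIM
LDHA
NONO
PGAM1
RPL11
RPL19
RPL29
RPL37A
RPL4
RPS11
RPS24
RPS3
RPS9
SRP14
TPT1
YWHAB
YWHAE
G6PD
TKT
CLTC
GUK1
IPO8
POP4
CDKN1B
ELF1
ABL1
CASC3
GADD45A
FAU
NACA
PFN1
RPL9
RPS27A
EIF2B1
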