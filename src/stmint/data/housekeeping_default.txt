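ACTB
GAPDH
B2M
RPL13A
RPS18
TUBB
PPIA
HPRT1
TBP
GUSB
PGK1
YWHAZ
SDHA
UBC
RPLP0
EEF1A1
POLR2A
TFRC
HMBS
RPL32
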