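ACTB
GAPDH
B2M
TUBB
PPIA
UBC
UBB
HPRT1
TBP
GUSB
PGK1
LDHA
SDHA
YWHAZ
RPLP0
TFRC
HMBS
EEF1A1
EEF2
RPL4
RPL5
RPL7
RPL8
RPL9
RPL10
RPL11
RPL13
RPL13A
RPL14
RPL15
RPL18
RPL19
RPL23
RPL27
RPL30
RPL32
RPL37
RPL38
RPLP1
RPLP2
RPS2
RPS3
RPS4X
RPS5
RPS6
RPS8
RPS9
RPS11
RPS12
RPS13
RPS14
RPS15
RPS16
RPS18
RPS19
RPS23
RPS25
RPS27
GPI
ENO1
PGAM1
TPI1
ALDOA
PKM
VIM
HNRNPC
NPM1
NACA
BTF3
PABPC1
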