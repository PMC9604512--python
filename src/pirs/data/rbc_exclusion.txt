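RN7SL1
RN7SL2
HBA1
HBA2
HBB
HBQ1
HBZ
HBD
HBG2
HBE1
HBG1
HBM
MIR3648-1
MIR3648-2
AC104389.6
AC010507.1
SLC25A37
SLC4A1
NRGN
SNCA
BNIP3L
EPB42
ALAS2
BPGM
OSBP2
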