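OsGI	LOC_Os01g08700
Ghd7	LOC_Os07g15770
Hd1	LOC_Os06g16370
Ehd1	LOC_Os10g32600
RFT1	LOC_Os06g06300
Hd3a	LOC_Os06g06320
OsMADS14	LOC_Os03g54160
OsMADS15	LOC_Os07g01820
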