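LOC_Os09g12750	G2-like
LOC_Os01g13740	G2-like
LOC_Os02g08440	G2-like
LOC_Os04g48390	G2-like
LOC_Os06g24070	G2-like
LOC_Os01g09280	MYB
LOC_Os01g12860	MYB
LOC_Os04g43680	MYB
LOC_Os01g09900	bHLH
LOC_Os02g02820	bHLH
LOC_Os03g08930	NAC
LOC_Os01g01430	NAC
LOC_Os05g39720	WRKY
LOC_Os01g14440	WRKY
LOC_Os02g43790	ERF
LOC_Os03g08460	C2H2
LOC_Os01g39020	HSF
LOC_Os05g31380	GRAS
LOC_Os02g33610	Trihelix
LOC_Os06g10880	bZIP
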