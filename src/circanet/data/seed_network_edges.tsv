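# Seed clock network fixture (synthetic stand-in for a curated 43-gene extended
# core-clock network: 14 core-clock genes plus 29 curated direct interactors).
gene1	gene2	sign	refs
ARNTL	PER1	activation	
CLOCK	PER1	activation	
ARNTL	PER2	activation	
CLOCK	PER2	activation	
ARNTL	PER3	activation	
CLOCK	PER3	activation	
ARNTL	CRY1	activation	
CLOCK	CRY1	activation	
ARNTL	CRY2	activation	
CLOCK	CRY2	activation	
ARNTL	NR1D1	activation	
CLOCK	NR1D1	activation	
ARNTL	NR1D2	activation	
CLOCK	NR1D2	activation	
ARNTL	RORA	activation	
CLOCK	RORA	activation	
ARNTL	RORC	activation	
CLOCK	RORC	activation	
ARNTL	DBP	activation	
CLOCK	DBP	activation	
ARNTL	BHLHE40	activation	
CLOCK	BHLHE40	activation	
ARNTL	BHLHE41	activation	
CLOCK	BHLHE41	activation	
ARNTL	TEF	activation	
CLOCK	TEF	activation	
ARNTL	HLF	activation	
CLOCK	HLF	activation	
ARNTL	NFIL3	activation	
CLOCK	NFIL3	activation	
ARNTL	NAMPT	activation	
CLOCK	NAMPT	activation	
NPAS2	PER1	activation	
NPAS2	PER2	activation	
NPAS2	CRY1	activation	
NPAS2	NR1D1	activation	
ARNTL2	PER1	activation	
ARNTL2	NR1D1	activation	
ARNTL2	DBP	activation	
PER1	ARNTL	inhibition	
PER1	CLOCK	inhibition	
PER2	ARNTL	inhibition	
PER2	CLOCK	inhibition	
PER3	ARNTL	inhibition	
PER3	CLOCK	inhibition	
CRY1	ARNTL	inhibition	
CRY1	CLOCK	inhibition	
CRY2	ARNTL	inhibition	
CRY2	CLOCK	inhibition	
NR1D1	ARNTL	inhibition	
NR1D1	CLOCK	inhibition	
NR1D1	NFIL3	inhibition	
NR1D1	ARNTL2	inhibition	
NR1D2	ARNTL	inhibition	
NR1D2	CLOCK	inhibition	
NR1D2	NFIL3	inhibition	
NR1D2	ARNTL2	inhibition	
RORA	ARNTL	activation	
RORB	ARNTL	activation	
RORC	ARNTL	activation	
RORA	ARNTL2	activation	
RORC	NR1D1	activation	
CSNK1D	PER1	other	
CSNK1D	PER2	other	
CSNK1E	PER1	other	
CSNK1E	PER2	other	
CSNK1E	CRY1	other	
CSNK2A1	PER2	other	
CSNK2A1	ARNTL	other	
FBXL3	CRY1	inhibition	
FBXL3	CRY2	inhibition	
FBXL21	CRY1	other	
BTRC	PER1	inhibition	
BTRC	PER2	inhibition	
FBXW11	PER2	inhibition	
GSK3B	ARNTL	other	
GSK3B	PER2	other	
GSK3B	CRY2	other	
GSK3B	NR1D1	other	
SIRT1	PER2	inhibition	
SIRT1	ARNTL	other	
EP300	ARNTL	activation	
CREBBP	ARNTL	activation	
CREB1	PER1	activation	
CREB1	PER2	activation	
PRKAA1	CRY1	other	
PRKAA1	CSNK1E	other	
WDR5	PER1	other	
NONO	PER1	other	
SFPQ	PER1	other	
PARP1	CLOCK	other	
HDAC3	NR1D1	other	
PPARGC1A	ARNTL	activation	
NAMPT	SIRT1	activation	
DBP	PER1	activation	
NFIL3	PER1	inhibition	
BHLHE40	ARNTL	inhibition	
BHLHE41	CLOCK	inhibition	
TIMELESS	CRY1	other	
TIMELESS	PER1	other	
MYC	ARNTL	inhibition	
NFKB1	ARNTL	other	
TEF	PER1	activation	
HLF	PER1	activation	
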