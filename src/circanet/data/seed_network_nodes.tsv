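# Seed clock network fixture (synthetic stand-in for a curated 43-gene extended
# core-clock network: 14 core-clock genes plus 29 curated direct interactors).
gene	layer
CLOCK	CCN
NPAS2	CCN
ARNTL	CCN
ARNTL2	CCN
PER1	CCN
PER2	CCN
PER3	CCN
CRY1	CCN
CRY2	CCN
NR1D1	CCN
NR1D2	CCN
RORA	CCN
RORB	CCN
RORC	CCN
CREB1	ECCN
PRKAA1	ECCN
CSNK1D	ECCN
CSNK1E	ECCN
CSNK2A1	ECCN
GSK3B	ECCN
FBXL3	ECCN
FBXL21	ECCN
BTRC	ECCN
FBXW11	ECCN
SIRT1	ECCN
EP300	ECCN
CREBBP	ECCN
WDR5	ECCN
NONO	ECCN
PARP1	ECCN
DBP	ECCN
NFIL3	ECCN
TEF	ECCN
HLF	ECCN
BHLHE40	ECCN
BHLHE41	ECCN
TIMELESS	ECCN
NFKB1	ECCN
MYC	ECCN
HDAC3	ECCN
PPARGC1A	ECCN
NAMPT	ECCN
SFPQ	ECCN
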