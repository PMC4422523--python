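entrezID	symbol	reverba	reverbb	reverbab	rora	rorg	rorag	circadian	high_A	long_T	short_T	bmal1	ml_similar	disease
102	ADAM10		x											x
328	APEX1	x												
350	APOH	x	x	x	x	x	x	x						
466	ATF1			x										
471	ATIC	x										x		x
551	AVP							x						x
813	CALU		x		x									
885	CCK	x												
996	CDC27			x										
1108	CHD4			x				x						
1195	CLK1							x						x
1386	ATF2												x	
1452	CSNK1A1	x	x	x						x				
1459	CSNK2A2			x										
1499	CTNNB1	x		x										x
1642	DDB1			x					x			x		
1656	DDX6			x				x					x	
1660	DHX9							x					x	
1855	DVL1			x										
1859	DYRK1A	x	x	x										x
1915	EEF1A1	x	x		x									
1994	ELAVL1												x	
2177	FANCD2			x										x
2547	XRCC6	x												
2875	GPT	x	x	x										
2905	GRIN2C	x	x	x										
3308	HSPA4					x							x	
3454	IFNAR1		x	x		x		x						
4089	SMAD4	x						x						x
4297	MLL	x	x	x										x
4299	AFF1	x	x	x										
4670	HNRNPM							x						
4691	NCL				x			x		x			x	
4830	NME1	x		x									x	x
4836	NMT1	x	x					x						
5430	POLR2A				x									
5469	MED1			x		x							x	
5478	PPIA			x										
5599	MAPK8	x		x						x				
5663	PSEN1				x			x						x
5725	PTBP1	x		x										
5931	RBBP7												x	
5980	REV3L			x										
6125	RPL5			x										x
6667	SP1	x		x		x								
6868	ADAM17							x						x
7248	TSC1	x		x										x
7341	SUMO1							x						x
7520	XRCC5		x											
7994	KAT6A	x		x										
8021	NUP214			x										x
8202	NCOA3	x	x	x										
8491	MAP4K3	x	x					x						
8615	USO1	x	x	x										
8648	NCOA1							x						
9318	COPS2										x			
9611	NCOR1	x	x	x										
9612	NCOR2	x	x	x										
10059	DNM1L							x					x	x
10432	RBM14		x	x	x	x	x							
10499	NCOA2	x												
10615	SPAG5		x		x	x	x							
10664	CTCF			x										x
10725	NFAT5			x										
10728	PTGES3			x				x						
11331	PHB2							x						
23013	SPEN	x		x										x
26959	HBP1	x												
27113	BBC3	x		x										
27327	TNRC6A		x											
28996	HIPK2	x	x											
51514	DTL	x	x	x										
54464	XRN1			x										
55031	USP47		x	x										
57786	RBAK				x									
79664	NARG2	x	x	x	x									
90480	GADD45GIP1			x										
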