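# Keyword lexicon mapping annotation descriptions to transcription-factor
# families (20 families of the olive fruit/abscission-zone comparison).
# Lower priority number = matched first; priorities must be unique.
priority	pattern	family
10	MADS[- ]?box|AGAMOUS|\bTAGL?\d|\bAGL\d+\b|\bSVP\b|\bRIN\b	MADS-box
20	\bWRKY	WRKY
30	heat[- ]?shock\s+(transcription\s+)?factor|\bHSF	HSF
40	\bGRAS\b|\bSCARECROW\b	GRAS
50	GAGA[- ]binding|\bBBR\b|\bBPC\d?\b	GAGA-binding
60	\bEIN3\b|\bEIL\d?\b	EIN3/EIL
70	\bE2F\d?\b|\bDPa?\b	E2F/DP
80	CCAAT[- ]binding|\bNF-Y	CCAAT-binding
90	\bCAMTA\d?\b|calmodulin[- ]binding transcription	CAMTA
100	\bC2H2	C2H2L
110	Aux/IAA|\bIAA\d+\b|auxin[- ]induced protein	Aux/IAA
120	\bAP2\b|\bERF\d*\b|ethylene[- ]respons\w+ (element[- ]binding )?factor|\bDREB	AP2/ERF
130	\bNAC\b|\bA?NAC\d+\b	NAC
140	\bMYB	MYB
150	bZIP|basic leucine zipper|\bHY5\b|\bRF2[ab]\b|\bTGA\d?\b|\bVIP1\b	bZIP
160	bHLH|helix[- ]loop[- ]helix|\bMYC\d?\b	bHLH
170	homeobox|homeodomain|\bHB[- ]?\d+\b|\bKNOX\b|\bWOX\d*\b	homeobox
180	zinc[- ]finger|\bZF\b|\bZFP\d*\b|\bDOF\d*\.?\d*\b	ZF
190	SBP[- ]box|\bSPL\d+\b|squamosa promoter[- ]binding	SBP-box
200	auxin response factor|\bARF\d+\b	ARF
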