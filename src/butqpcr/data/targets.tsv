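# Curated human-gut butyrate producers carrying the but gene
# (butyryl-CoA:acetate CoA-transferase); NCBI nucleotide and protein
# accessions. cluster = primer-panel cluster where the taxon is named in the
# study text; left empty when per-strain membership is not stated.
taxon	nt_accession	prot_accession	cluster
Anaerostipes caccae DSM 14662	ABAX03000012	WP_006566634	F
Anaerobutyricum hallii DSM 3353	ACEP01000025	EEG37758	E
Anaerostipes hadrus DSM 3319	AMEY01000089	EKY19441	F
Clostridiales bacterium KA00134	LTAF01000006	KXO16903
Clostridium sp. JN-9	CP035280	QAT39812
Clostridium sp. M62/1	ACFX02000051	EFE10856	C
Clostridium sp. SS2/1	ABGC03000034	EDS21983
[Clostridium] propionicum DSM 1682	FQUA01000004	SHE65336
[Clostridium] symbiosum ATCC 14940	AWSU01000039	ERI80067	C
[Clostridium] symbiosum WAL-14673	ADLR01000107	EGB17928	C
Coprococcus eutactus 2789STDY5608829	CYYZ01000002	CUN77211	B
Coprococcus eutactus 2789STDY5608843	CYYJ01000005	CUO17024	B
Coprococcus eutactus 2789STDY5608888	CYYE01000001	CUN69525	B
Coprococcus eutactus 2789STDY5834963	CYXU01000007	CUN05838	B
Eubacterium callanderi FD	FRBP01000012	SHM18802
Eubacterium limosum ATCC 8486	CP019962	ARD67787
Eubacterium limosum SA11	CP011914	ALU15403
Eubacterium maltosivorans YI	CP029487	QCT73558
Eubacterium sp. 14-2	ASSS01000012	EOT23498
Faecalibacterium prausnitzii 942/30-2	CP026548	AXA81262	C
Faecalibacterium prausnitzii A2165 CG447_00005	CP022479	ATO98751	C
Faecalibacterium prausnitzii A2-165 FAEPRAA2165_01562	ACOP02000044	EEU96797	C
Faecalibacterium prausnitzii APC918/95b	CP030777	AXB28579	C
Faecalibacterium prausnitzii Indica	CP023819	ATL89114	C
Faecalibacterium prausnitzii KLE1255	AECU01000083	EFQ07628	C
Flavonifractor plautii 2789STDY5834892	CZAS01000006	CUP57950	A
Flavonifractor plautii 2789STDY5834932	CZBD01000023	CUQ37563	A
Lachnospiraceae bacterium 3-1	ASST01000018	EOS23550	D
Lachnospiraceae bacterium 3-1	ASST01000032	EOS21051	D
Lachnospiraceae bacterium A2	ASSX01000004	EOS48506	D
Lachnospiraceae bacterium A4	ASSR01000007	EOS36856	D
Lachnospiraceae bacterium MD335	ASSW01000016	EOS51721	D
Lachnospiraceae bacterium TF01-11	LLKB01000001	KQC86641	D
Pseudoflavonifractor capillosus ATCC 29799	AAXG02000004	EDN01706	A
Roseburia intestinalis L1-82	ABYJ02000099	EEV00989	D
Roseburia inulinivorans DSM 16841	ACFY01000152	EEG92587	D
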