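sample_id	gene	region	state	breakpoint_tag
obs001	ABCA1	5'UTR – 3'UTR	het_deletion	
obs002	ABCA1	Exons 47–48	het_deletion	
obs003	ABCA1	Exons 8–31	het_deletion	
obs004	ABCA1	Exons 8–31	het_deletion	
obs005	ABCA1	Exons 4–7	duplication	
obs006	ABCA1	Exon 4	het_deletion	
obs007	ABCG1	Non-coding exon 1 – 3'UTR	duplication	
obs008	ABCG1	Non-coding exon 1 – 3'UTR	duplication	
obs009	ABCG8	Exons 4–6	duplication	
obs010	ABCG8	Exons 4–6	duplication	
obs011	ABCG8	Exons 4–6	duplication	
obs012	AGPAT2	Exons 2–4	het_deletion	
obs013	AGPAT2	5'UTR – exon 1	het_deletion	
obs014	ANGPTL3	Exon 3 – 3'UTR	het_deletion	
obs015	APOA5	5'UTR – 3'UTR	het_deletion	
obs016	APOA5;APOA4	5'UTR – 3'UTR, 5'UTR – 3'UTR	duplication	
obs017	APOB	5'UTR – 3'UTR	duplication	
obs018	APOC2	Non-coding exon 1	hom_deletion	
obs019	BLK	Exon 2 – 3'UTR	duplication	
obs020	BLK	Exon 2 – 3'UTR	duplication	
obs021	BLK	Exon 2 – 3'UTR	duplication	
obs022	BLK	Exon 2 – 3'UTR	duplication	
obs023	BLK	Exon 2 – 3'UTR	duplication	
obs024	BLK	Exon 2 – 3'UTR	duplication	
obs025	BLK	Exon 2 – 3'UTR	duplication	
obs026	BLK	Exon 2 – 3'UTR	duplication	
obs027	BLK	Exon 2 – 3'UTR	duplication	
obs028	BLK	Exon 2 – 3'UTR	duplication	
obs029	BLK	Exon 2 – 3'UTR	duplication	
obs030	BLK	Exon 2 – 3'UTR	duplication	
obs031	BLK	Exon 2 – 3'UTR	duplication	
obs032	BLK	Exon 2 – 3'UTR	duplication	
obs033	BLK	Exon 2 – 3'UTR	duplication	
obs034	BLK	Exon 2 – 3'UTR	duplication	
obs035	BLK	Exon 2 – 3'UTR	duplication	
obs036	BLK	Exon 2 – 3'UTR	duplication	
obs037	BLK	Exon 2 – 3'UTR	duplication	
obs038	BLK	Exon 2 – 3'UTR	duplication	
obs039	BLK	Exon 2 – 3'UTR	duplication	
obs040	BLK	Exon 2 – 3'UTR	duplication	
obs041	BLK	Exon 2 – 3'UTR	duplication	
obs042	BLK	Exon 2 – 3'UTR	duplication	
obs043	BLK	Exon 2 – 3'UTR	duplication	
obs044	BLK	Exon 2 – 3'UTR	duplication	
obs045	BLK	Exon 2 – 3'UTR	duplication	
obs046	BLK	Exon 2 – 3'UTR	duplication	
obs047	BLK	Exon 2 – 3'UTR	duplication	
obs048	BLK	Exon 10	duplication	
obs049	CAV2	5'UTR – exon 1	duplication	
obs050	CETP	5'UTR – exon 2	het_deletion	
obs051	CIDEC	Exon 4 – 3'UTR	het_deletion	
obs052	CIDEC	Alternative non-coding exon 1a	het_deletion	
obs053	CIDEC	Alternative non-coding exon 1a	het_deletion	
obs054	CIDEC	Alternative non-coding exon 1a	het_deletion	
obs055	CREB3L3	5'UTR – exon 2	het_deletion	
obs056	CREB3L3	5'UTR – 3'UTR	duplication	
obs057	CREB3L3	5'UTR – 3'UTR	duplication	
obs058	CREB3L3	Exons 3–4	het_deletion	
obs059	CREB3L3	Exon 5	het_deletion	
obs060	GCK	5'UTR – alternative exon 1	het_deletion	
obs061	GCK	5'UTR – alternative exon 1	het_deletion	
obs062	GCK	5'UTR – alternative exon 1	het_deletion	
obs063	GCK	5'UTR – alternative exon 1	het_deletion	
obs064	GCK	5'UTR – alternative exon 1	het_deletion	
obs065	GCK	5'UTR – alternative exon 1	duplication	
obs066	GPIHBP1	5'UTR – 3'UTR	hom_deletion	
obs067	GPIHBP1	5'UTR – 3'UTR	hom_deletion	
obs068	GPIHBP1	5'UTR – 3'UTR	hom_deletion	
obs069	GPIHBP1	Exons 3–4	het_deletion	
obs070	GPIHBP1	Exons 3–4	het_deletion	
obs071	GPIHBP1	Exons 3–4	het_deletion	
obs072	HNF1B	5'UTR – 3'UTR	het_deletion	
obs073	HNF1B	5'UTR – 3'UTR	het_deletion	
obs074	HNF1B	5'UTR – 3'UTR	het_deletion	
obs075	HNF4A	5'UTR – exon 1	het_deletion	
obs076	HNF4A	5'UTR – 3'UTR	het_deletion	
obs077	LDLR	5'UTR – exon 1	het_deletion	
obs078	LDLR	5'UTR – intron 1	het_deletion	
obs079	LDLR	5'UTR – intron 1	het_deletion	
obs080	LDLR	5'UTR – intron 1	het_deletion	
obs081	LDLR	5'UTR – intron 1	het_deletion	
obs082	LDLR	5'UTR – intron 1	het_deletion	
obs083	LDLR	5'UTR – intron 1	het_deletion	
obs084	LDLR	5'UTR – intron 1	het_deletion	
obs085	LDLR	5'UTR – intron 1	het_deletion	
obs086	LDLR	5'UTR – intron 1	het_deletion	
obs087	LDLR	5'UTR – intron 1	het_deletion	
obs088	LDLR	5'UTR – intron 1	het_deletion	
obs089	LDLR	5'UTR – intron 1	het_deletion	
obs090	LDLR	5'UTR – intron 1	het_deletion	
obs091	LDLR	5'UTR – intron 1	het_deletion	
obs092	LDLR	5'UTR – intron 1	het_deletion	
obs093	LDLR	5'UTR – intron 1	het_deletion	
obs094	LDLR	5'UTR – intron 1	het_deletion	
obs095	LDLR	5'UTR – intron 1	het_deletion	
obs096	LDLR	5'UTR – intron 1	het_deletion	
obs097	LDLR	5'UTR – intron 1	het_deletion	
obs098	LDLR	5'UTR – intron 1	het_deletion	
obs099	LDLR	5'UTR – intron 1	het_deletion	
obs100	LDLR	5'UTR – intron 1	het_deletion	
obs101	LDLR	5'UTR – intron 1	het_deletion	
obs102	LDLR	5'UTR – intron 1	het_deletion	
obs103	LDLR	5'UTR – intron 1	het_deletion	
obs104	LDLR	5'UTR – intron 1	het_deletion	
obs105	LDLR	5'UTR – intron 1	het_deletion	
obs106	LDLR	5'UTR – intron 1	het_deletion	
obs107	LDLR	5'UTR – intron 1	het_deletion	
obs108	LDLR	5'UTR – intron 1	het_deletion	
obs109	LDLR	5'UTR – intron 1	het_deletion	
obs110	LDLR	5'UTR – intron 1	het_deletion	
obs111	LDLR	5'UTR – exon 2	het_deletion	
obs112	LDLR	5'UTR – exon 2	het_deletion	
obs113	LDLR	5'UTR – exon 2	het_deletion	
obs114	LDLR	5'UTR – exon 6	het_deletion	
obs115	LDLR	Exons 2–3	het_deletion	
obs116	LDLR	Exons 2–6	duplication	
obs117	LDLR	Exons 2–6	het_deletion	
obs118	LDLR	Exons 2–6	het_deletion	
obs119	LDLR	Exons 2–6	het_deletion	
obs120	LDLR	Exons 2–6	het_deletion	
obs121	LDLR	Exons 2–6	het_deletion	
obs122	LDLR	Exons 2–6	het_deletion	
obs123	LDLR	Exons 2–6	het_deletion	
obs124	LDLR	Exons 2–6	het_deletion	
obs125	LDLR	Exons 2–6	het_deletion	
obs126	LDLR	Exons 2–6	het_deletion	
obs127	LDLR	Exons 3–6	het_deletion	
obs128	LDLR	Exons 3–6	het_deletion	
obs129	LDLR	Exons 3–6	het_deletion	
obs130	LDLR	Exons 3–6	het_deletion	
obs131	LDLR	Exons 4–6	het_deletion	
obs132	LDLR	Exons 5–6	het_deletion	
obs133	LDLR	Exon 7	duplication	
obs134	LDLR	Exons 9–10	het_deletion	
obs135	LDLR	Exons 11–12	duplication	a
obs136	LDLR	Exons 11–12	duplication	b
obs137	LDLR	Exons 11–12	het_deletion	
obs138	LDLR	Exons 13–14	het_deletion	
obs139	LDLR	Exons 13–15	het_deletion	
obs140	LDLR	Exon 16 – 3'UTR	het_deletion	
obs141	LDLR	Exon 17 – 3'UTR	het_deletion	
obs142	LDLR	Exon 17 – 3'UTR	het_deletion	
obs143	LDLR	Exon 17 – 3'UTR	het_deletion	
obs144	LDLR	Exon 17 – 3'UTR	het_deletion	
obs145	LDLR	Exon 17 – 3'UTR	het_deletion	
obs146	LDLR	Exons 18 – 3'UTR	het_deletion	
obs147	LDLRAP1	5'UTR – exon 1	duplication	
obs148	LIPA	Exon 9 – 3'UTR	het_deletion	
obs149	LIPA	Exon 4	het_deletion	
obs150	LIPA	Exon 4	het_deletion	
obs151	LIPC	5'UTR – exon 1	het_deletion	
obs152	LIPC	5'UTR – exon 1	het_deletion	
obs153	LIPC	5'UTR – exon 1	het_deletion	
obs154	LIPC	5'UTR – exon 1	het_deletion	
obs155	LIPC	5'UTR – exon 1	het_deletion	
obs156	LIPC	5'UTR – exon 1	het_deletion	
obs157	LMF1	Exon 6	het_deletion	
obs158	LMF1	Exon 6	het_deletion	
obs159	LPIN1	Exons 2–4	het_deletion	
obs160	LPIN1	Alternative exon 6	het_deletion	
obs161	LPIN1	Exon 18	het_deletion	
obs162	LPIN1	Exon 18	het_deletion	
obs163	LPIN1	Exon 18	het_deletion	
obs164	LPIN1	Exons 18–19	het_deletion	
obs165	LPL	5'UTR – exon 1	het_deletion	
obs166	LPL	5'UTR – exon 2	het_deletion	
obs167	LPL	5'UTR – exon 2	het_deletion	
obs168	LPL	5'UTR – exon 2	het_deletion	
obs169	MFN2	Exons 4–6	duplication	
obs170	MTTP	5'UTR – 3'UTR	het_deletion	
obs171	MTTP	Exon 10	het_deletion	
obs172	MTTP	Exons 10–15	hom_deletion	
obs173	MTTP	Exons 10–15	hom_deletion	
obs174	MTTP	Exons 10–15	het_deletion	
obs175	NPC1L1	Exons 6–10	het_deletion	
obs176	PCSK9	5'UTR – 3'UTR	duplication	
obs177	PCSK9	5'UTR – 3'UTR	duplication	
obs178	PCSK9	5'UTR – 3'UTR	duplication	
obs179	PCSK9	5'UTR – 3'UTR	duplication	
obs180	PCSK9	5'UTR – 3'UTR	duplication	
obs181	PLIN1	Exon 3 – 3'UTR	duplication	
obs182	PLIN1	Exon 8	het_deletion	
obs183	PLIN1	Exon 8	het_deletion	
obs184	PLIN1	Exon 2	het_deletion	
obs185	PNPLA2	5'UTR – 3'UTR	duplication	
obs186	POLD1	5'UTR	duplication	
obs187	POLD1	5'UTR	duplication	
obs188	PPARA	Alternative non-coding exon 1 – 3'UTR	duplication	
obs189	WRN	Exon 3	het_deletion	
obs190	WRN	Exons 9–11	het_deletion	
obs191	WRN	Exon 10	duplication	
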