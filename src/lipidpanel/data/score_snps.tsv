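snp_id	trait	raising_allele	other_allele	beta	raising_allele_freq	chromosome	position
rs9000001	LDL	T	C	0.1436	0.151	chr17	500001000
rs9000002	LDL	C	G	0.0611	0.182	chr19	500002000
rs9000003	LDL	A	G	0.1389	0.44	chr5	500003000
rs9000004	LDL	G	C	0.0973	0.351	chr22	500004000
rs9000005	LDL	G	C	0.0896	0.628	chr4	500005000
rs9000006	LDL	C	A	0.1447	0.105	chr2	500006000
rs9000007	LDL	A	T	0.0977	0.37	chr17	500007000
rs9000008	LDL	A	C	0.114	0.446	chr17	500008000
rs9000009	LDL	G	A	0.1715	0.676	chr5	500009000
rs9000010	LDL	T	A	0.0933	0.496	chr8	500010000
rs9000011	TG	G	T	0.1039	0.463	chr10	500011000
rs9000012	TG	G	C	0.1003	0.653	chr15	500012000
rs9000013	TG	C	T	0.0602	0.269	chr22	500013000
rs9000014	TG	T	G	0.0721	0.309	chr20	500014000
rs9000015	TG	A	C	0.1085	0.273	chr7	500015000
rs9000016	TG	A	T	0.106	0.102	chr21	500016000
rs9000017	TG	G	A	0.0378	0.376	chr5	500017000
rs9000018	TG	A	G	0.0531	0.582	chr22	500018000
rs9000019	TG	C	G	0.0354	0.482	chr10	500019000
rs9000020	TG	A	T	0.0983	0.432	chr21	500020000
rs9000021	TG	C	G	0.094	0.606	chr2	500021000
rs9000022	TG	C	T	0.0301	0.434	chr3	500022000
rs9000023	TG	G	T	0.1018	0.324	chr9	500023000
rs9000024	TG	T	G	0.0527	0.249	chr18	500024000
rs9000025	TG	T	C	0.0334	0.409	chr4	500025000
rs9000026	TG	G	T	0.1002	0.271	chr6	500026000
rs9000027	HDL	T	A	0.0445	0.378	chr19	500027000
rs9000028	HDL	C	A	0.0396	0.231	chr20	500028000
rs9000029	HDL	T	A	0.0263	0.668	chr8	500029000
rs9000030	HDL	C	G	0.0682	0.225	chr19	500030000
rs9000031	HDL	G	C	0.0722	0.164	chr20	500031000
rs9000032	HDL	C	T	0.0681	0.297	chr8	500032000
rs9000033	HDL	A	C	0.0395	0.55	chr15	500033000
rs9000034	HDL	T	A	0.0223	0.282	chr18	500034000
rs9000035	HDL	A	T	0.0761	0.351	chr13	500035000
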