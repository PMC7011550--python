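{
  "comment": "Ordered gene/zygosity-to-diagnosis rules; first match wins. phenotype_context null = any phenotype.",
  "rules": [
    {"phenotype_context": ["FH", "HoFH", "familial_combined"], "gene_set": ["LDLR", "APOB", "PCSK9", "LDLRAP1"], "required_allelic_state": "biallelic", "diagnosis_label": "HoFH"},
    {"phenotype_context": null, "gene_set": ["ABCG5", "ABCG8"], "required_allelic_state": "biallelic", "diagnosis_label": "Sitosterolemia"},
    {"phenotype_context": null, "gene_set": ["LIPA"], "required_allelic_state": "biallelic", "diagnosis_label": "LALD"},
    {"phenotype_context": null, "gene_set": ["APOC2"], "required_allelic_state": "biallelic", "diagnosis_label": "APOC2 deficiency"},
    {"phenotype_context": null, "gene_set": ["LPL", "APOC2", "APOA5", "GPIHBP1", "LMF1"], "required_allelic_state": "biallelic", "diagnosis_label": "Familial chylomicronemia syndrome"},
    {"phenotype_context": ["hypobetalipoproteinemia"], "gene_set": ["MTTP"], "required_allelic_state": "biallelic", "diagnosis_label": "Abetalipoproteinemia"},
    {"phenotype_context": ["hypobetalipoproteinemia"], "gene_set": ["APOB"], "required_allelic_state": "biallelic", "diagnosis_label": "Homozygous FHBL"},
    {"phenotype_context": ["hypobetalipoproteinemia"], "gene_set": ["SAR1B"], "required_allelic_state": "biallelic", "diagnosis_label": "Chylomicron retention disease"},
    {"phenotype_context": ["hypoalphalipoproteinemia"], "gene_set": ["LCAT"], "required_allelic_state": "biallelic", "diagnosis_label": "LCAT deficiency"},
    {"phenotype_context": ["hypoalphalipoproteinemia"], "gene_set": ["APOA1"], "required_allelic_state": "biallelic", "diagnosis_label": "Apo A-I deficiency"},
    {"phenotype_context": ["hypoalphalipoproteinemia"], "gene_set": ["ABCA1"], "required_allelic_state": "biallelic", "diagnosis_label": "Tangier disease"},
    {"phenotype_context": ["FH", "HoFH", "familial_combined"], "gene_set": ["LDLR", "APOB", "PCSK9"], "required_allelic_state": "heterozygous", "diagnosis_label": "HeFH"},
    {"phenotype_context": ["lipodystrophy"], "gene_set": ["LMNA"], "required_allelic_state": "either", "diagnosis_label": "FPLD2"},
    {"phenotype_context": ["lipodystrophy"], "gene_set": ["PPARG"], "required_allelic_state": "either", "diagnosis_label": "FPLD3"},
    {"phenotype_context": ["MODY"], "gene_set": ["HNF1A"], "required_allelic_state": "either", "diagnosis_label": "MODY3"},
    {"phenotype_context": ["MODY"], "gene_set": ["GCK"], "required_allelic_state": "either", "diagnosis_label": "MODY2"}
  ]
}
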