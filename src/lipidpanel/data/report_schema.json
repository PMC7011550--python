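{
  "type": "object",
  "required": [
    "sample_id",
    "referral_phenotype",
    "report_category",
    "diagnosis",
    "rare_variant_findings",
    "disclosed_score",
    "notes"
  ],
  "properties": {
    "sample_id": {"type": "string"},
    "referral_phenotype": {"type": "string"},
    "report_category": {"type": "string", "enum": ["a_diagnosis", "b_confirmation", "c_relevant", "d_negative"]},
    "diagnosis": {"type": ["string", "null"]},
    "rare_variant_findings": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["gene", "description", "zygosity", "tier"],
        "properties": {
          "gene": {"type": "string"},
          "description": {"type": "string"},
          "zygosity": {"type": "string"},
          "tier": {"type": "string"}
        }
      }
    },
    "disclosed_score": {
      "type": ["object", "null"],
      "required": ["trait", "weighted_score", "allele_tally", "n_snps_used", "percentile", "extreme"],
      "properties": {
        "trait": {"type": "string", "enum": ["LDL", "TG", "HDL"]},
        "weighted_score": {"type": "number"},
        "allele_tally": {"type": "integer"},
        "n_snps_used": {"type": "integer"},
        "percentile": {"type": ["number", "null"]},
        "extreme": {"type": ["boolean", "null"]}
      }
    },
    "notes": {"type": "string"}
  }
}
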