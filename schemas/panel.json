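{
  "name": "panel",
  "description": "Variant panel; simulated panels add a true_weight column.",
  "required_columns": [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "freq"
  ],
  "columns": {
    "snp_id": "variant identifier",
    "chrom": "chromosome",
    "pos": "1-based position",
    "effect_allele": "dosage-coded allele",
    "other_allele": "the other allele",
    "freq": "coded-allele frequency",
    "true_weight": "(simulated panels) true raw weight"
  }
}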