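{
  "name": "sumstats",
  "description": "GWAS summary statistics for the exposure, one row per variant.",
  "required_columns": [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "eaf"
  ],
  "columns": {
    "snp_id": "variant identifier (unique)",
    "chrom": "chromosome (integer)",
    "pos": "1-based base-pair position",
    "effect_allele": "allele the beta refers to",
    "other_allele": "the non-effect allele",
    "beta": "per-allele effect on the exposure",
    "se": "standard error of beta (> 0)",
    "pvalue": "association p-value in (0, 1]",
    "eaf": "effect-allele frequency in (0, 1)"
  }
}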