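{
  "name": "scores",
  "description": "Polygenic scores per person.",
  "required_columns": [
    "person_id",
    "family_id",
    "role",
    "raw",
    "standardized"
  ],
  "columns": {
    "person_id": "person id",
    "family_id": "trio id",
    "role": "mother | father | child",
    "raw": "sum of beta_j * dosage_j over retained variants",
    "standardized": "raw score standardized within role (mean 0, SD 1)"
  }
}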