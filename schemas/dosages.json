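{
  "name": "dosages",
  "description": "Wide dosage table: id columns then one dosage column per variant (values in [0, 2]); role in {mother, father, child}.",
  "required_columns": [
    "person_id",
    "family_id",
    "role"
  ],
  "columns": {
    "person_id": "unique person id",
    "family_id": "trio id",
    "role": "mother | father | child",
    "<snp_id>...": "one additive dosage column per variant, values in [0, 2]"
  }
}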