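{
  "name": "phenotypes",
  "description": "One row per trio; outcomes and covariates; missing as empty field.",
  "required_columns": [
    "family_id",
    "child_sex",
    "birth_year",
    "edu_mother_years",
    "edu_father_years"
  ],
  "columns": {
    "family_id": "trio id",
    "child_sex": "0 = female, 1 = male",
    "birth_year": "year",
    "edu_mother_years": "mother's education in years",
    "edu_father_years": "father's education in years",
    "smfq": "child depressive traits score (0-26)",
    "scared": "child anxiety score (0-10)",
    "adhd_total": "child ADHD total (0-54) = inattention + hyperactivity",
    "adhd_inattention": "subscale (0-27)",
    "adhd_hyperactivity": "subscale (0-27)",
    "mother_depanx / father_depanx": "parental depressive/anxiety trait scores",
    "mother_adhd / father_adhd": "parental ADHD trait scores",
    "mother_smoking / father_smoking": "3-level ordinal (0 never, 1 stopped, 2 current)",
    "parity": "5-level ordinal (0..4+)",
    "batch_center / batch_chip": "genotyping batch labels",
    "pc<k>_<role>": "ancestry principal components per family member",
    "family_cluster": "genetic family cluster id (cluster-robust SEs)",
    "(missing)": "encoded as empty field"
  }
}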