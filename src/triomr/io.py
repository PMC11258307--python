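"""Tabular I/O: TSV readers/writers with the missing-as-empty convention,
run manifests, and lightweight schema validation."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_tsv",
    "write_tsv",
    "write_manifest",
    "config_hash",
    "SCHEMAS",
    "validate_frame",
]

SCHEMAS: dict[str, dict] = {
    "sumstats": {
        "required": ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                     "beta", "se", "pvalue", "eaf"],
        "description": "GWAS summary statistics for the exposure, one row per variant.",
    },
    "panel": {
        "required": ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "freq"],
        "description": "Variant panel; simulated panels add a true_weight column.",
    },
    "dosages": {
        "required": ["person_id", "family_id", "role"],
        "description": "Wide dosage table: id columns then one dosage column per variant "
                       "(values in [0, 2]); role in {mother, father, child}.",
    },
    "phenotypes": {
        "required": ["family_id", "child_sex", "birth_year",
                     "edu_mother_years", "edu_father_years"],
        "description": "One row per trio; outcomes and covariates; missing as empty field.",
    },
    "scores": {
        "required": ["person_id", "family_id", "role", "raw", "standardized"],
        "description": "Polygenic scores per person.",
    },
}


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[""], keep_default_na=True)


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def config_hash(obj) -> str:
    """Stable hash of a JSON-serializable config object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(path, config: dict, seeds: dict, outputs: list[str]) -> None:
    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seeds": seeds,
        "outputs": sorted(outputs),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def validate_frame(df: pd.DataFrame, schema: str) -> list[str]:
    """Return a list of column-level problems (empty when valid)."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    problems = []
    for col in SCHEMAS[schema]["required"]:
        if col not in df.columns:
            problems.append(f"missing required column {col!r}")
    if schema == "dosages" and "role" in df.columns:
        bad = set(df["role"].unique()) - {"mother", "father", "child"}
        if bad:
            problems.append(f"unknown role values: {sorted(bad)}")
    return problems
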