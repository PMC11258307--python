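"""Polygenic-index construction.

Allele harmonization against the genotype panel, greedy p-value-ordered
LD clumping, weighted additive scoring, and within-sample (per-role)
standardization.  Weights come from exposure GWAS summary statistics;
clumping follows the common greedy semantics: repeatedly take the
smallest-p unclaimed variant below the p threshold as an index and remove
unclaimed same-chromosome variants within the window whose LD r^2 with
the index reaches the r^2 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LdReference",
    "ClumpResult",
    "harmonize_alleles",
    "clump",
    "strict_subset",
    "score",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


class LdReference:
    """Pairwise LD r^2 lookup backed by a dense matrix keyed by variant id."""

    def __init__(self, ids: list[str], r2_matrix: np.ndarray):
        r2_matrix = np.asarray(r2_matrix, dtype=np.float64)
        if r2_matrix.shape != (len(ids), len(ids)):
            raise ValueError("r2 matrix shape must match the id list")
        self.ids = list(ids)
        self._index = {v: i for i, v in enumerate(self.ids)}
        self.matrix = r2_matrix

    @classmethod
    def from_dosages(cls, dosages: np.ndarray | pd.DataFrame,
                     ids: list[str] | None = None) -> "LdReference":
        """Empirical r^2 (squared Pearson correlation of dosages)."""
        if isinstance(dosages, pd.DataFrame):
            ids = list(dosages.columns) if ids is None else ids
            dosages = dosages.to_numpy(dtype=np.float64)
        if ids is None:
            raise ValueError("ids required for array input")
        d = np.asarray(dosages, dtype=np.float64)
        sd = d.std(axis=0)
        keepvar = np.where(sd > 0, sd, 1.0)
        z = (d - d.mean(axis=0)) / keepvar
        corr = (z.T @ z) / len(d)
        corr[sd == 0, :] = 0.0
        corr[:, sd == 0] = 0.0
        return cls(ids, corr**2)

    @classmethod
    def from_tsv(cls, path) -> "LdReference":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    def r2(self, a: str, b: str) -> float | None:
        """r^2 for a pair, or None if either variant is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.matrix[ia, ib])


@dataclass
class ClumpResult:
    """Retained variants in selection order plus a log of removals."""

    retained: list[str]
    params: dict = field(default_factory=dict)
    dropped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["snp_id", "reason", "index_variant"]))


def harmonize_alleles(sumstats: pd.DataFrame, panel: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align summary-stat effect alleles to the dosage-coded alleles.

    Variants absent from the panel are dropped; swapped alleles flip the
    beta sign (and EAF); strand flips are resolved via complements;
    strand-ambiguous (A/T, C/G) variants with effect-allele frequency in
    [0.4, 0.6] are dropped; irreconcilable pairs are dropped with a
    logged reason rather than raising.
    """
    panel_idx = panel.set_index("snp_id")
    rows, exclusions = [], []
    for rec in sumstats.itertuples(index=False):
        rid = rec.snp_id
        if rid not in panel_idx.index:
            exclusions.append((rid, "not_in_panel"))
            continue
        ea, oa = rec.effect_allele, rec.other_allele
        if {ea, oa} in _AMBIGUOUS and 0.4 <= rec.eaf <= 0.6:
            exclusions.append((rid, "strand_ambiguous"))
            continue
        pea = panel_idx.at[rid, "effect_allele"]
        poa = panel_idx.at[rid, "other_allele"]
        cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
        row = rec._asdict()
        if (ea, oa) == (pea, poa) or (cea, coa) == (pea, poa):
            pass
        elif (oa, ea) == (pea, poa) or (coa, cea) == (pea, poa):
            row["beta"] = -rec.beta
            row["eaf"] = 1.0 - rec.eaf
            row["effect_allele"], row["other_allele"] = oa, ea
        else:
            exclusions.append((rid, "irreconcilable_alleles"))
            continue
        rows.append(row)
    harmonized = pd.DataFrame(rows, columns=list(sumstats.columns))
    log = pd.DataFrame(exclusions, columns=["snp_id", "reason"])
    return harmonized, log


def clump(sumstats: pd.DataFrame, ld_reference: LdReference,
          p_threshold: float = 5.0e-8, r2_threshold: float = 0.01,
          window_kb: float = 10_000.0, missing_ld: str = "zero") -> ClumpResult:
    """Greedy LD clumping of ``sumstats`` (needs snp_id, chrom, pos, pvalue).

    Ties on p-value break by (chromosome, position) ascending.  The
    window is symmetric around the index variant and inclusive at the
    boundary.  A missing LD entry for an in-window pair is treated as
    r^2 = 0 with a warning (``missing_ld="zero"``) or raises
    (``missing_ld="error"``).
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    if not (0 <= r2_threshold <= 1):
        raise ValueError("r2_threshold must be in [0, 1]")
    cand = sumstats.loc[sumstats["pvalue"] < p_threshold,
                        ["snp_id", "chrom", "pos", "pvalue"]].copy()
    cand = cand.sort_values(["pvalue", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    window_bp = window_kb * 1000.0

    sids = cand["snp_id"].to_numpy()
    chroms = cand["chrom"].to_numpy()
    poss = cand["pos"].to_numpy()
    claimed = np.zeros(len(cand), dtype=bool)
    retained: list[str] = []
    dropped: list[tuple[str, str, str]] = []
    warned_missing = False

    for i in range(len(cand)):
        if claimed[i]:
            continue
        idx_id = sids[i]
        retained.append(idx_id)
        claimed[i] = True
        in_win = (~claimed) & (chroms == chroms[i]) & (np.abs(poss - poss[i]) <= window_bp)
        for j in np.nonzero(in_win)[0]:
            r2 = ld_reference.r2(idx_id, sids[j])
            if r2 is None:
                if missing_ld == "error":
                    raise KeyError(f"no LD entry for pair ({idx_id}, {sids[j]})")
                if not warned_missing:
                    warnings.warn("missing LD entries treated as r^2 = 0", stacklevel=2)
                    warned_missing = True
                r2 = 0.0
            if r2 >= r2_threshold:
                claimed[j] = True
                dropped.append((sids[j], "ld_with_index", idx_id))

    below = sumstats.loc[sumstats["pvalue"] >= p_threshold, "snp_id"]
    dropped.extend((s, "p_above_threshold", "") for s in below)
    return ClumpResult(
        retained=retained,
        params={"p_threshold": p_threshold, "r2_threshold": r2_threshold,
                "window_kb": window_kb},
        dropped=pd.DataFrame(dropped, columns=["snp_id", "reason", "index_variant"]),
    )


def strict_subset(sumstats: pd.DataFrame, ld_reference: LdReference,
                  p_threshold: float = 5.0e-8, window_kb: float = 10_000.0) -> ClumpResult:
    """Clump at the stringent r^2 = 0.001 threshold (independent-SNP subset)."""
    return clump(sumstats, ld_reference, p_threshold=p_threshold,
                 r2_threshold=0.001, window_kb=window_kb)


def score(dosages: pd.DataFrame, sumstats: pd.DataFrame, clump_result: ClumpResult,
          per_role: bool = True) -> pd.DataFrame:
    """Weighted additive polygenic score over the retained variants.

    ``dosages`` is the wide per-person table (person_id, family_id, role,
    one column per variant).  Raw score = sum_j beta_j * dosage_j;
    standardized within the scored sample, by role when ``per_role``.
    Missing dosages for a retained variant raise (no genotype
    missingness in an analytic sample).
    """
    retained = clump_result.retained
    missing = [v for v in retained if v not in dosages.columns]
    if missing:
        raise KeyError(f"dosage table lacks retained variants: {missing[:5]}")
    weights = sumstats.set_index("snp_id").loc[retained, "beta"].to_numpy()
    G = dosages[retained].to_numpy(dtype=np.float64)
    if np.isnan(G).any():
        raise ValueError("missing dosage values for retained variants")
    raw = G @ weights if retained else np.zeros(len(dosages))
    out = dosages[["person_id", "family_id", "role"]].copy()
    out["raw"] = raw

    def _std(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else x * 0.0

    if per_role:
        out["standardized"] = out.groupby("role")["raw"].transform(_std)
    else:
        out["standardized"] = _std(out["raw"])
    return out
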