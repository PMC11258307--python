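"""Two-sample summary-data Mendelian randomization.

Per-variant SNP-outcome associations are estimated in-cohort from linear
models that mutually adjust for mother, father, and child genotype (plus
the within-family covariate set); the mother and father dosage
coefficients are the parental SNP-outcome betas.  Conditioning on the
child's genotype is what makes the resulting summary-MR estimates
"within-family".  SNP-exposure betas come from the discovery GWAS and
stay on its reporting scale.

Estimators: inverse-variance weighted (fixed and multiplicative
random-effects), MR-Egger (slope + intercept, with the exposure betas
oriented non-negative), the weighted median, and a mode-based estimator
(weighted Gaussian-kernel density over Wald ratios, Silverman bandwidth
scaled by ``phi``).  Median/mode SEs come from a parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pgi import ClumpResult, strict_subset
from .onesample import _design_columns, _sandwich_factor, ModelSpec

__all__ = [
    "MrEstimate",
    "EggerResult",
    "estimate_conditional_snp_assocs",
    "ivw",
    "egger",
    "weighted_median",
    "mode_based",
    "run_twosample_suite",
]


@dataclass
class MrEstimate:
    """A summary-MR estimator's output."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    q_stat: float | None = None
    se_fixed: float | None = None


@dataclass
class EggerResult:
    slope: MrEstimate
    intercept: MrEstimate


def _wrap(method: str, est: float, se: float, n: int, q: float | None = None,
          se_fixed: float | None = None) -> MrEstimate:
    crit = stats.norm.ppf(0.975)
    if se > 0:
        p = 2.0 * stats.norm.sf(abs(est) / se)
    else:
        p = 1.0 if est == 0 else 0.0
    return MrEstimate(method=method, estimate=float(est), se=float(se),
                      ci_low=float(est - crit * se), ci_high=float(est + crit * se),
                      p=float(p), n_snps=n, q_stat=q, se_fixed=se_fixed)


def estimate_conditional_snp_assocs(cohort, variant_ids: list[str], outcome: str,
                                    sumstats: pd.DataFrame,
                                    outcome_values: np.ndarray | None = None
                                    ) -> pd.DataFrame:
    """Mutually adjusted per-SNP outcome associations.

    For each variant: outcome ~ mother dosage + father dosage + child
    dosage + within-family covariates, with cluster-robust SEs (clusters =
    genetic family).  The covariate block is partialled out once
    (Frisch-Waugh), which leaves the three dosage coefficients, their
    residuals, and their cluster sandwich block exact.  Monomorphic
    variants are dropped.  Returns one row per (variant, parent) with the
    exposure beta/SE merged in from ``sumstats``.
    """
    pheno = cohort.phenotypes
    y = (pheno[outcome].to_numpy(dtype=np.float64)
         if outcome_values is None else np.asarray(outcome_values, dtype=np.float64))
    if np.isnan(y).any():
        raise ValueError("outcome contains missing values; supply imputed values")
    spec = ModelSpec(spec="wfmr", outcome=outcome)
    C = _design_columns(pheno, spec).to_numpy(dtype=np.float64)
    clusters = pd.factorize(pheno["family_cluster"].to_numpy()
                            if "family_cluster" in pheno.columns
                            else pheno["family_id"].to_numpy())[0]
    g = int(clusters.max()) + 1
    n = len(y)
    k_full = C.shape[1] + 3

    idx = {v: i for i, v in enumerate(cohort.panel["snp_id"])}
    Q, _ = np.linalg.qr(C)
    y_t = y - Q @ (Q.T @ y)
    ss = sumstats.set_index("snp_id")

    rows = []
    for vid in variant_ids:
        j = idx[vid]
        G = np.column_stack([cohort.dosages["mother"][:, j],
                             cohort.dosages["father"][:, j],
                             cohort.dosages["child"][:, j]]).astype(np.float64)
        if (G.std(axis=0) == 0).any():
            continue
        Gt = G - Q @ (Q.T @ G)
        XtX = Gt.T @ Gt
        beta = np.linalg.solve(XtX, Gt.T @ y_t)
        u = y_t - Gt @ beta
        S = np.zeros((g, 3))
        np.add.at(S, clusters, Gt * u[:, None])
        A_inv = np.linalg.inv(XtX)
        V = _sandwich_factor(n, k_full, g) * A_inv @ (S.T @ S) @ A_inv
        se = np.sqrt(np.clip(np.diag(V), 0.0, None))
        for role, b, s in zip(("mother", "father", "child"), beta, se):
            rows.append({"snp_id": vid, "parent": role,
                         "beta_out": float(b), "se_out": float(s),
                         "beta_exp": float(ss.at[vid, "beta"]),
                         "se_exp": float(ss.at[vid, "se"])})
    return pd.DataFrame(rows)


def _check(assocs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = assocs["beta_exp"].to_numpy(dtype=np.float64)
    by = assocs["beta_out"].to_numpy(dtype=np.float64)
    sx = assocs["se_exp"].to_numpy(dtype=np.float64)
    sy = assocs["se_out"].to_numpy(dtype=np.float64)
    if len(bx) < 1:
        raise ValueError("need at least one variant")
    if (sy <= 0).any():
        raise ValueError("outcome SEs must be positive")
    return bx, by, sx, sy


def ivw(assocs: pd.DataFrame) -> MrEstimate:
    """Inverse-variance weighted estimate: weighted regression of outcome
    betas on exposure betas through the origin, weights 1/se_out^2.
    Random-effects SE scales the fixed SE by max(1, sqrt(Q/(J-1)))."""
    bx, by, _, sy = _check(assocs)
    w = 1.0 / sy**2
    denom = float((w * bx**2).sum())
    est = float((w * bx * by).sum()) / denom
    se_fixed = 1.0 / np.sqrt(denom)
    q = float((w * (by - est * bx) ** 2).sum())
    J = len(bx)
    scale = max(1.0, np.sqrt(q / (J - 1))) if J > 1 else 1.0
    se = se_fixed * scale
    return _wrap("ivw", est, se, J, q=q, se_fixed=se_fixed)


def egger(assocs: pd.DataFrame, min_snps: int = 3) -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure betas with an
    unconstrained intercept; exposure betas oriented non-negative first.
    The intercept estimates directional pleiotropy.  ``min_snps`` can be
    lowered for closed-form fixtures."""
    bx, by, _, sy = _check(assocs)
    J = len(bx)
    if J < min_snps:
        raise ValueError(f"MR-Egger requires >= {min_snps} variants, got {J}")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(J), bx])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, WX.T @ by)
    resid = by - X @ coef
    q = float((w * resid**2).sum())
    cov_fixed = np.linalg.inv(XtWX)
    scale = max(1.0, q / (J - 2)) if J > 2 else 1.0
    cov = cov_fixed * scale
    se = np.sqrt(np.diag(cov))
    se_f = np.sqrt(np.diag(cov_fixed))
    return EggerResult(
        slope=_wrap("egger_slope", coef[1], se[1], J, q=q, se_fixed=se_f[1]),
        intercept=_wrap("egger_intercept", coef[0], se[0], J, q=q, se_fixed=se_f[0]),
    )


def _ratio_weights(assocs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    bx, by, _, sy = _check(assocs)
    ratios = by / bx
    w = bx**2 / sy**2  # delta-method inverse variance of the Wald ratio
    return ratios, w


def _median_point(ratios: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, ww = ratios[order], w[order]
    ww = ww / ww.sum()
    S = np.cumsum(ww)
    p = S - ww / 2.0
    if len(r) == 1:
        return float(r[0])
    return float(np.interp(0.5, p, r))


def weighted_median(assocs: pd.DataFrame, n_boot: int = 1000,
                    seed: int = 0) -> MrEstimate:
    """Weighted-median estimator over per-variant Wald ratios.

    Ratios are ordered, cumulative weight probabilities p_j = S_j - s_j/2
    computed, and the estimate linearly interpolated at p = 0.5; the SE
    comes from a parametric bootstrap of (beta_out, beta_exp)."""
    bx, by, sx, sy = _check(assocs)
    ratios, w = _ratio_weights(assocs)
    est = _median_point(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.normal(size=len(bx))
        bys = by + sy * rng.normal(size=len(by))
        bxs = np.where(bxs == 0, 1e-12, bxs)
        boots[b] = _median_point(bys / bxs, bxs**2 / sy**2)
    return _wrap("weighted_median", est, float(boots.std(ddof=1)), len(bx))


def _mode_point(ratios: np.ndarray, w: np.ndarray, phi: float) -> float:
    if len(ratios) == 1 or np.ptp(ratios) == 0:
        return float(ratios[0])
    w = w / w.sum()
    sd = float(ratios.std(ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    h = 0.9 * min(sd, iqr / 1.34 if iqr > 0 else sd) * len(ratios) ** (-0.2) * phi
    if h <= 0:
        return float(ratios[np.argmax(w)])
    grid = np.linspace(ratios.mean() - 5 * sd, ratios.mean() + 5 * sd, 512)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_based(assocs: pd.DataFrame, phi: float = 1.0, n_boot: int = 1000,
               seed: int = 0) -> MrEstimate:
    """Mode-based estimator: argmax of a weighted Gaussian-kernel density
    over Wald ratios (Silverman bandwidth x ``phi``), bootstrap SE."""
    bx, by, sx, sy = _check(assocs)
    ratios, w = _ratio_weights(assocs)
    est = _mode_point(ratios, w, phi)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.normal(size=len(bx))
        bys = by + sy * rng.normal(size=len(by))
        bxs = np.where(bxs == 0, 1e-12, bxs)
        boots[b] = _mode_point(bys / bxs, bxs**2 / sy**2, phi)
    return _wrap("mode", est, float(boots.std(ddof=1)), len(bx))


def run_twosample_suite(cohort, sumstats: pd.DataFrame, clump_result: ClumpResult,
                        ld_reference, outcomes: list[str], strict: bool = False,
                        outcome_values: dict[str, np.ndarray] | None = None,
                        n_boot: int = 500, seed: int = 0) -> pd.DataFrame:
    """Full grid of summary-MR estimates per (parent, outcome, estimator).

    ``strict`` reruns on the r^2 = 0.001 subset of the clumped panel
    (necessarily a subset of the full set).  ``outcome_values`` supplies
    imputed outcome vectors keyed by outcome name.
    """
    variant_ids = list(clump_result.retained)
    if strict:
        sub_stats = sumstats[sumstats["snp_id"].isin(variant_ids)]
        sub = strict_subset(sub_stats, ld_reference,
                            p_threshold=clump_result.params.get("p_threshold", 5e-8),
                            window_kb=clump_result.params.get("window_kb", 10_000.0))
        variant_ids = [v for v in sub.retained if v in set(clump_result.retained)]
    rows = []
    for outcome in outcomes:
        vals = outcome_values.get(outcome) if outcome_values else None
        assocs = estimate_conditional_snp_assocs(cohort, variant_ids, outcome,
                                                 sumstats, outcome_values=vals)
        for parent in ("mother", "father"):
            sub_a = assocs[assocs["parent"] == parent]
            ests = [ivw(sub_a)]
            if len(sub_a) >= 3:
                eg = egger(sub_a)
                ests.extend([eg.slope, eg.intercept])
            ests.append(weighted_median(sub_a, n_boot=n_boot, seed=seed))
            ests.append(mode_based(sub_a, n_boot=n_boot, seed=seed))
            for e in ests:
                rows.append({"parent": parent, "outcome": outcome, "estimator": e.method,
                             "estimate": e.estimate, "se": e.se, "ci_low": e.ci_low,
                             "ci_high": e.ci_high, "p": e.p, "n_snps": e.n_snps,
                             "q_stat": e.q_stat,
                             "snp_set": "strict" if strict else "full"})
    return pd.DataFrame(rows)
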