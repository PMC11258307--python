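"""Multiple imputation by chained equations with predictive mean matching,
Rubin's-rules pooling, and questionnaire score utilities.

PMM here is the type-1 matching variant: a Bayesian parameter draw from
the normal approximation of the regression posterior produces predictions
for the missing rows, donors are the ``knn`` observed rows with the
closest point-estimate predictions, and the imputed value is the observed
value of one uniformly chosen donor.  Ordinal variables are imputed by
PMM on their integer codes, which preserves the observed support.
Pooling uses Rubin's rules with the Barnard-Rubin small-sample degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ImputationConfig",
    "CompletedData",
    "pmm_impute_column",
    "chained_impute",
    "pool_rubin",
    "prorate_score",
]


@dataclass
class ImputationConfig:
    """MICE settings.  ``variables`` maps column -> role ("continuous" or
    "ordinal"); ``predictors`` are complete covariate columns entering
    every imputation model; ``passive`` maps a total column to the
    component columns whose sum defines it post-imputation."""

    m: int = 5
    knn: int = 10
    n_cycles: int = 10
    variables: dict[str, str] | None = None
    predictors: list[str] | None = None
    passive: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.knn < 1:
            raise ValueError("knn must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass
class CompletedData:
    """The m completed datasets plus the per-cell imputation indicator."""

    datasets: list[pd.DataFrame]
    indicator: pd.DataFrame
    config: ImputationConfig

    @property
    def m(self) -> int:
        return len(self.datasets)


def pmm_impute_column(y: np.ndarray, X: np.ndarray, knn: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Impute the missing entries of ``y`` by predictive mean matching on
    the complete predictor matrix ``X`` (an intercept is added here)."""
    y = np.asarray(y, dtype=np.float64)
    X = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=np.float64)])
    obs = ~np.isnan(y)
    mis = ~obs
    if not mis.any():
        return y.copy()
    n_obs, k = int(obs.sum()), X.shape[1]
    if n_obs < k + knn:
        raise ValueError(
            f"only {n_obs} observed values for {k} parameters + knn={knn}; "
            "use fewer predictors or a smaller donor pool")

    Xo, yo = X[obs], y[obs]
    beta_hat, _, _, _ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta_hat
    dof = max(n_obs - k, 1)
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(Xo.T @ Xo)
    cov = sigma2 * XtX_inv
    # symmetrize against accumulated rounding before the posterior draw
    cov = 0.5 * (cov + cov.T)
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
        beta_star = beta_hat + L @ rng.normal(size=k)
    except np.linalg.LinAlgError:
        beta_star = beta_hat

    pred_obs = Xo @ beta_hat
    pred_mis = X[mis] @ beta_star

    order = np.argsort(pred_obs, kind="mergesort")
    sorted_pred = pred_obs[order]
    sorted_y = yo[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    n_miss = len(pred_mis)
    donors = np.empty(n_miss)
    pick = rng.integers(0, knn, size=n_miss)
    for i in range(n_miss):
        lo = max(pos[i] - knn, 0)
        hi = min(pos[i] + knn, n_obs)
        window = np.arange(lo, hi)
        d = np.abs(sorted_pred[window] - pred_mis[i])
        nearest = window[np.argsort(d, kind="mergesort")[:knn]]
        donors[i] = sorted_y[nearest[pick[i] % len(nearest)]]

    out = y.copy()
    out[mis] = donors
    return out


def _resolve_model(data: pd.DataFrame, config: ImputationConfig
                   ) -> tuple[dict[str, str], list[str]]:
    passive_cols = set(config.passive)
    if config.variables is not None:
        variables = dict(config.variables)
    else:
        variables = {c: "continuous" for c in data.columns
                     if c not in passive_cols
                     and pd.api.types.is_numeric_dtype(data[c])
                     and data[c].isna().any()}
    for col in variables:
        if data[col].isna().all():
            raise ValueError(f"variable {col!r} is 100% missing; cannot impute")
    if config.predictors is not None:
        predictors = list(config.predictors)
    else:
        predictors = [c for c in data.columns
                      if c not in variables and c not in passive_cols
                      and pd.api.types.is_numeric_dtype(data[c])
                      and not data[c].isna().any()]
    for col in predictors:
        if data[col].isna().any():
            raise ValueError(f"predictor {col!r} has missing values")
    return variables, predictors


def chained_impute(data: pd.DataFrame, config: ImputationConfig) -> CompletedData:
    """MICE: visit incomplete variables in increasing-missingness order for
    ``n_cycles`` sweeps, ``m`` times with independent randomness.

    Passive totals (e.g. an ADHD total formed from imputed inattention
    and hyperactivity subscales) are recomputed after each completed
    dataset rather than imputed directly.
    """
    variables, predictors = _resolve_model(data, config)
    rng = np.random.default_rng(config.seed)
    indicator = data[list(variables)].isna() if variables else pd.DataFrame(index=data.index)

    order = sorted(variables, key=lambda c: (data[c].isna().mean(), c))
    datasets = []
    for _ in range(config.m):
        work = data.copy()
        # initialize by random draws from the observed values
        for col in order:
            mis = work[col].isna()
            if mis.any():
                obs_vals = work.loc[~mis, col].to_numpy()
                work.loc[mis, col] = rng.choice(obs_vals, size=int(mis.sum()))
        if variables:
            for _cycle in range(config.n_cycles):
                for col in order:
                    mis = indicator[col].to_numpy()
                    if not mis.any():
                        continue
                    others = [c for c in order if c != col]
                    Xcols = predictors + others
                    y = data[col].to_numpy(dtype=np.float64).copy()
                    y[mis] = np.nan
                    X = work[Xcols].to_numpy(dtype=np.float64)
                    filled = pmm_impute_column(y, X, config.knn, rng)
                    if variables[col] == "ordinal":
                        filled = np.round(filled)
                    work[col] = filled
        for total, parts in config.passive.items():
            work[total] = work[parts].sum(axis=1)
        datasets.append(work)
    return CompletedData(datasets=datasets, indicator=indicator, config=config)


def pool_rubin(estimates: np.ndarray | pd.DataFrame,
               variances: np.ndarray | pd.DataFrame,
               df_com: float = np.inf) -> pd.DataFrame:
    """Rubin's rules over ``m`` per-dataset estimates and squared SEs.

    Inputs are (m, k) arrays (or DataFrames with term columns).  Returns a
    per-term frame with the pooled estimate Q̄, within-variance W̄,
    between-variance B, total variance T = W̄ + (1 + 1/m) B, the
    Barnard-Rubin adjusted degrees of freedom (given the complete-data
    degrees of freedom ``df_com``; +inf recovers the classic large-sample
    df), a t-based 95% CI and two-sided p-value.
    """
    names = None
    if isinstance(estimates, pd.DataFrame):
        names = list(estimates.columns)
        estimates = estimates.to_numpy()
    if isinstance(variances, pd.DataFrame):
        variances = variances.to_numpy()
    Q = np.atleast_2d(np.asarray(estimates, dtype=np.float64))
    U = np.atleast_2d(np.asarray(variances, dtype=np.float64))
    if Q.shape != U.shape:
        raise ValueError("estimates and variances must have identical shape")
    m = Q.shape[0]
    if m < 2:
        raise ValueError("pooling requires m >= 2 imputed datasets")

    qbar = Q.mean(axis=0)
    wbar = U.mean(axis=0)
    B = Q.var(axis=0, ddof=1)
    T = wbar + (1.0 + 1.0 / m) * B

    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * B / wbar
        df_old = (m - 1) * (1.0 + 1.0 / np.where(r > 0, r, np.inf)) ** 2
        lam = (1.0 + 1.0 / m) * B / np.where(T > 0, T, np.inf)
        if np.isinf(df_com):
            df = df_old
        else:
            df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    df = np.where(B > 0, df, np.inf if np.isinf(df_com) else df_com)

    se = np.sqrt(T)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, qbar / se, np.inf * np.sign(qbar))
    finite_df = np.where(np.isfinite(df), df, 1e12)
    p = 2.0 * stats.t.sf(np.abs(tstat), finite_df)
    crit = stats.t.ppf(0.975, finite_df)
    out = pd.DataFrame({
        "estimate": qbar, "within": wbar, "between": B, "total": T,
        "se": se, "df": df, "ci_low": qbar - crit * se,
        "ci_high": qbar + crit * se, "p": p,
    })
    if names is not None:
        out.index = names
    return out


def prorate_score(items, n_items: int, min_frac: float = 0.8):
    """Prorated questionnaire summary score.

    With observed fraction >= ``min_frac``: mean(observed) * n_items;
    otherwise missing.  Accepts a 1-D item vector (returns a scalar) or a
    2-D persons x items array/DataFrame (returns a vector).
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    arr = np.asarray(items, dtype=np.float64)
    if arr.ndim == 1:
        obs = ~np.isnan(arr)
        if obs.sum() / n_items >= min_frac:
            return float(arr[obs].mean() * n_items)
        return np.nan
    obs = ~np.isnan(arr)
    counts = obs.sum(axis=1)
    frac = counts / n_items
    sums = np.where(obs, arr, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / np.where(counts > 0, counts, 1)
    out = np.where(frac >= min_frac, means * n_items, np.nan)
    return out
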