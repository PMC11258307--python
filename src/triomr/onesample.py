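"""One-sample model fitting: the four model specifications with
cluster-robust inference.

The four specifications mirror a trio analysis of parental education
effects on standardized child outcomes:

``ols_minimal``
    outcome ~ mother/father education years + child sex + birth year +
    genotyping batch dummies + ancestry PCs.
``ols_adjusted``
    adds measured confounders: parental depressive/anxiety and ADHD
    trait scores, parental smoking, parity.
``mr``
    two-stage least squares with both parents' education instrumented by
    their polygenic indexes; the child's PGI excluded.
``wfmr``
    within-family MR: the ``mr`` model with the child's own PGI added as
    a covariate, blocking the direct-genetic-transmission path.

All models use a clustered sandwich with the finite-sample factor
G/(G-1) * (N-1)/(N-k) (Stata's clustered ``vce(robust)`` convention),
clusters being genetic family IDs.  Normal critical values are the
default; t-based inference is available per config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .impute import CompletedData, pool_rubin

__all__ = [
    "ModelSpec",
    "FitResult",
    "IvDiagnostics",
    "standardize_outcome",
    "fit_ols_cluster",
    "fit_2sls_cluster",
    "first_stage_diagnostics",
    "run_spec",
]

SPECS = ("ols_minimal", "ols_adjusted", "mr", "wfmr")

MINIMAL_COVARIATES = ["child_sex", "birth_year"]
CONFOUNDER_COVARIATES = ["mother_depanx", "father_depanx", "mother_adhd", "father_adhd"]
CATEGORICAL_CONFOUNDERS = ["mother_smoking", "father_smoking", "parity"]
BATCH_COLUMNS = ["batch_center", "batch_chip"]


@dataclass
class ModelSpec:
    """One of the four model specifications plus sensitivity options."""

    spec: str
    outcome: str
    sqrt_transform: bool = False
    sex: int | None = None
    per_parent: str | None = None  # "mother"/"father": single-exposure MR mode
    use_t: bool = False

    def __post_init__(self) -> None:
        if self.spec not in SPECS:
            raise ValueError(f"spec must be one of {SPECS}, got {self.spec!r}")
        if self.per_parent not in (None, "mother", "father"):
            raise ValueError("per_parent must be None, 'mother' or 'father'")
        if self.per_parent is not None and self.spec not in ("mr", "wfmr"):
            raise ValueError("per_parent applies to MR specs only")


@dataclass
class IvDiagnostics:
    """Instrument-strength diagnostics per endogenous regressor."""

    f_stat: dict[str, float]
    conditional_f: dict[str, float]
    partial_r2: dict[str, float]


@dataclass
class FitResult:
    """Per-term estimates with cluster-robust inference.

    ``params`` is indexed by term with columns estimate, se, ci_low,
    ci_high, p.  For instrumented fits ``diagnostics`` carries first-stage
    F statistics and partial R^2.
    """

    params: pd.DataFrame
    n: int
    n_clusters: int
    diagnostics: IvDiagnostics | None = None
    dropped_columns: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.params.loc[name]


def standardize_outcome(x, mean: float | None = None, sd: float | None = None):
    """Standardize to mean 0, SD 1 (sample SD) over the provided scope.

    ``mean``/``sd`` may be supplied (e.g. observed-data moments applied
    identically across imputed datasets); otherwise they are computed from
    the non-missing values of ``x``.  A constant column raises.
    """
    arr = np.asarray(x, dtype=np.float64)
    obs = arr[~np.isnan(arr)]
    if len(obs) < 2:
        raise ValueError("need >= 2 non-missing values to standardize")
    if mean is None:
        mean = float(obs.mean())
    if sd is None:
        sd = float(obs.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant column")
    out = (arr - mean) / sd
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    return out


def _sandwich_factor(n: int, k: int, g: int) -> float:
    return (g / (g - 1.0)) * ((n - 1.0) / (n - k))


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns that are (numerically) linearly dependent, keeping the
    earliest columns; warns when anything is removed."""
    A = X.to_numpy(dtype=np.float64)
    cols = list(X.columns)
    norms = np.linalg.norm(A, axis=0)
    scaled = A / np.where(norms > 0, norms, 1.0)
    G = scaled.T @ scaled
    keep: list[int] = []
    dropped: list[str] = []
    tol = 1e-8
    for j in range(A.shape[1]):
        if norms[j] == 0:
            dropped.append(cols[j])
            continue
        if not keep:
            keep.append(j)
            continue
        sub = G[np.ix_(keep, keep)]
        cross = G[np.ix_(keep, [j])]
        sol = np.linalg.lstsq(sub, cross, rcond=None)[0]
        resid = G[j, j] - float((cross.T @ sol).item())
        if resid > tol:
            keep.append(j)
        else:
            dropped.append(cols[j])
    if dropped:
        warnings.warn(f"dropped collinear columns: {dropped}", stacklevel=3)
    return X.iloc[:, keep], dropped


def _ci_p(est: np.ndarray, se: np.ndarray, use_t: bool, dof: float) -> tuple:
    crit = stats.t.ppf(0.975, dof) if use_t else stats.norm.ppf(0.975)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.inf * np.sign(est))
    if use_t:
        p = 2.0 * stats.t.sf(np.abs(z), dof)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(se > 0, p, np.where(est == 0.0, 1.0, 0.0))
    return est - crit * se, est + crit * se, p


def fit_ols_cluster(y, X: pd.DataFrame, clusters, use_t: bool = False) -> FitResult:
    """OLS with cluster-robust (sandwich) standard errors via statsmodels.

    ``X`` must include any intercept column the caller wants; collinear
    columns (e.g. redundant batch dummies) are dropped with a warning.
    """
    y = np.asarray(y, dtype=np.float64)
    clusters = np.asarray(clusters)
    X2, dropped = _drop_collinear(X)
    groups = pd.factorize(clusters)[0]
    g = int(groups.max()) + 1
    if g < 2:
        raise ValueError("need at least 2 clusters")
    res = sm.OLS(y, X2.to_numpy(dtype=np.float64)).fit(
        cov_type="cluster",
        cov_kwds={"groups": groups, "use_correction": True},
        use_t=False,
    )
    est = np.asarray(res.params)
    se = np.asarray(res.bse)
    lo, hi, p = _ci_p(est, se, use_t, g - 1)
    params = pd.DataFrame(
        {"estimate": est, "se": se, "ci_low": lo, "ci_high": hi, "p": p},
        index=list(X2.columns),
    )
    return FitResult(params=params, n=len(y), n_clusters=g, dropped_columns=dropped)


def _cluster_meat(scores: np.ndarray, groups: np.ndarray, g: int) -> np.ndarray:
    k = scores.shape[1]
    S = np.zeros((g, k))
    np.add.at(S, groups, scores)
    return S.T @ S


def fit_2sls_cluster(y, endog: pd.DataFrame, instruments: pd.DataFrame,
                     exog: pd.DataFrame, clusters, use_t: bool = False,
                     diagnostics: bool = True) -> FitResult:
    """Two-stage least squares with cluster-robust SEs.

    The structural regressors are [exog, endog]; the instrument set is
    [exog, instruments].  Sandwich SEs use the structural residuals
    y - X beta-hat (not second-stage OLS residuals) with the same
    finite-sample factor as the OLS fit.
    """
    y = np.asarray(y, dtype=np.float64)
    if instruments.shape[1] < endog.shape[1]:
        raise ValueError("under-identified: fewer instruments than endogenous regressors")
    exog2, dropped = _drop_collinear(exog)
    X = pd.concat([exog2, endog], axis=1)
    Z = pd.concat([exog2, instruments], axis=1)
    Xa = X.to_numpy(dtype=np.float64)
    Za = Z.to_numpy(dtype=np.float64)
    groups = pd.factorize(np.asarray(clusters))[0]
    g = int(groups.max()) + 1
    if g < 2:
        raise ValueError("need at least 2 clusters")

    # first-stage projection X-hat = P_Z X via least squares for stability
    coef, _, rank, _ = np.linalg.lstsq(Za, Xa, rcond=None)
    if rank < Za.shape[1]:
        warnings.warn("instrument matrix is rank deficient", stacklevel=2)
    Xhat = Za @ coef
    XtX = Xhat.T @ Xhat
    try:
        beta = np.linalg.solve(XtX, Xhat.T @ y)
    except np.linalg.LinAlgError as exc:
        raise ValueError("first-stage rank failure") from exc

    u = y - Xa @ beta  # structural residuals
    n, k = Xa.shape
    A_inv = np.linalg.inv(XtX)
    meat = _cluster_meat(Xhat * u[:, None], groups, g)
    V = _sandwich_factor(n, k, g) * A_inv @ meat @ A_inv
    se = np.sqrt(np.clip(np.diag(V), 0.0, None))
    lo, hi, p = _ci_p(beta, se, use_t, g - 1)
    params = pd.DataFrame(
        {"estimate": beta, "se": se, "ci_low": lo, "ci_high": hi, "p": p},
        index=list(X.columns),
    )
    diag = None
    if diagnostics:
        diag = first_stage_diagnostics(endog, instruments, exog2, clusters)
    return FitResult(params=params, n=n, n_clusters=g, diagnostics=diag,
                     dropped_columns=dropped)


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0


def first_stage_diagnostics(endog: pd.DataFrame, instruments: pd.DataFrame,
                            exog: pd.DataFrame, clusters) -> IvDiagnostics:
    """First-stage instrument-strength diagnostics.

    Plain F: classical excluded-instrument F from each exposure's first
    stage including all instruments,
    F = (delta R^2 / q) / ((1 - R^2_full) / (n - k)).
    Conditional F: Sanderson-Windmeijer-style — the other endogenous
    regressor is partialled out of the exposure via its own instrument's
    fitted value before testing the exposure's own instrument.
    Partial R^2: increment in first-stage R^2 from adding the exposure's
    own instrument to the covariate-only model.
    """
    Xe = exog.to_numpy(dtype=np.float64)
    names = list(endog.columns)
    inames = list(instruments.columns)
    q = instruments.shape[1]
    f_stat: dict[str, float] = {}
    cond_f: dict[str, float] = {}
    partial: dict[str, float] = {}
    n = len(endog)
    Zall = np.column_stack([Xe, instruments.to_numpy(dtype=np.float64)])
    for i, name in enumerate(names):
        x = endog[name].to_numpy(dtype=np.float64)
        k_full = Zall.shape[1]
        r2_full = _r2(x, Zall)
        r2_red = _r2(x, Xe)
        f_stat[name] = ((r2_full - r2_red) / q) / ((1.0 - r2_full) / (n - k_full))

        own = instruments.iloc[:, min(i, q - 1)].to_numpy(dtype=np.float64)
        Z_own = np.column_stack([Xe, own])
        partial[name] = _r2(x, Z_own) - r2_red

        others = [j for j in range(len(names)) if j != i]
        if others and q > len(others):
            oth_fit = []
            for j in others:
                zj = instruments.iloc[:, min(j, q - 1)].to_numpy(dtype=np.float64)
                Zj = np.column_stack([Xe, zj])
                cj, _, _, _ = np.linalg.lstsq(Zj, endog.iloc[:, j].to_numpy(dtype=np.float64),
                                              rcond=None)
                oth_fit.append(Zj @ cj)
            Xc = np.column_stack([Xe] + oth_fit)
            cc, _, _, _ = np.linalg.lstsq(Xc, x, rcond=None)
            r = x - Xc @ cc
            k_c = Z_own.shape[1]
            r2c_full = _r2(r, Z_own)
            r2c_red = _r2(r, Xe)
            q_c = q - len(others)
            cond_f[name] = ((r2c_full - r2c_red) / q_c) / ((1.0 - r2c_full) / (n - k_c))
        else:
            cond_f[name] = f_stat[name]
    return IvDiagnostics(f_stat=f_stat, conditional_f=cond_f, partial_r2=partial)


def _design_columns(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Exogenous covariate design (intercept, sex/birth year, batch
    dummies, ancestry PCs; plus measured confounders for ols_adjusted)."""
    parts = [pd.Series(1.0, index=df.index, name="const")]
    covs = [c for c in MINIMAL_COVARIATES if c in df.columns]
    if spec.sex is not None and "child_sex" in covs:
        covs.remove("child_sex")
    parts.append(df[covs].astype(np.float64))
    for b in BATCH_COLUMNS:
        if b in df.columns:
            dummies = pd.get_dummies(df[b].astype("category"), prefix=b, drop_first=True)
            parts.append(dummies.astype(np.float64))
    pcs = [c for c in df.columns if c.startswith("pc")]
    if pcs:
        parts.append(df[pcs].astype(np.float64))
    if spec.spec == "ols_adjusted":
        parts.append(df[[c for c in CONFOUNDER_COVARIATES if c in df.columns]].astype(np.float64))
        for b in CATEGORICAL_CONFOUNDERS:
            if b in df.columns:
                dummies = pd.get_dummies(df[b].astype("category"), prefix=b, drop_first=True)
                parts.append(dummies.astype(np.float64))
    return pd.concat(parts, axis=1)


def _fit_single(df: pd.DataFrame, spec: ModelSpec, y: np.ndarray) -> FitResult:
    clusters = df["family_cluster"] if "family_cluster" in df.columns else df["family_id"]
    exog = _design_columns(df, spec)
    if spec.spec in ("ols_minimal", "ols_adjusted"):
        X = pd.concat([df[["edu_mother_years", "edu_father_years"]].astype(np.float64), exog],
                      axis=1)
        return fit_ols_cluster(y, X, clusters, use_t=spec.use_t)
    # MR specs
    if spec.per_parent is None:
        endog = df[["edu_mother_years", "edu_father_years"]].astype(np.float64)
        instr = df[["pgi_mother", "pgi_father"]].astype(np.float64)
    else:
        other = "father" if spec.per_parent == "mother" else "mother"
        endog = df[[f"edu_{spec.per_parent}_years"]].astype(np.float64)
        instr = df[[f"pgi_{spec.per_parent}"]].astype(np.float64)
        exog = pd.concat([exog, df[[f"pgi_{other}"]].astype(np.float64)], axis=1)
    if spec.spec == "wfmr":
        exog = pd.concat([exog, df[["pgi_child"]].astype(np.float64)], axis=1)
    return fit_2sls_cluster(y, endog, instr, exog, clusters, use_t=spec.use_t)


def run_spec(data, spec: ModelSpec, std_stats: tuple[float, float] | None = None) -> FitResult:
    """Fit one model specification on a single dataset or a stack of
    imputed datasets (pooled with Rubin's rules).

    The outcome is standardized with the observed-data mean/SD of the
    analytic sample — computed from the non-imputed cells when ``data``
    is a :class:`CompletedData` — and the same moments are applied to
    every imputed dataset so the estimand is fixed.  ``sqrt_transform``
    square-root-transforms the outcome (shifted to be nonnegative)
    before standardization; ``spec.sex`` restricts to one child sex.
    """
    if isinstance(data, CompletedData):
        datasets = data.datasets
        first = datasets[0]
        observed_mask = (~data.indicator[spec.outcome].to_numpy()
                         if spec.outcome in data.indicator.columns
                         else np.ones(len(first), dtype=bool))
    else:
        datasets = [data]
        first = data
        observed_mask = ~pd.isna(data[spec.outcome]).to_numpy()
    if spec.outcome not in first.columns:
        raise KeyError(f"outcome column {spec.outcome!r} not found")

    def transform(col: pd.Series) -> np.ndarray:
        v = col.to_numpy(dtype=np.float64)
        if spec.sqrt_transform:
            v = np.sqrt(np.clip(v - np.nanmin(v), 0.0, None))
        return v

    ref = transform(first[spec.outcome])[observed_mask]
    ref = ref[~np.isnan(ref)]
    if std_stats is None:
        std_stats = (float(ref.mean()), float(ref.std(ddof=1)))
    mu, sd = std_stats

    fits = []
    for ds in datasets:
        d = ds if spec.sex is None else ds[ds["child_sex"] == spec.sex]
        if not isinstance(data, CompletedData):
            d = d[~pd.isna(d[spec.outcome])]
        y = (transform(d[spec.outcome]) - mu) / sd
        fits.append(_fit_single(d, spec, y))

    if len(fits) == 1:
        return fits[0]
    terms = list(fits[0].params.index)
    est = pd.DataFrame([f.params["estimate"].to_numpy() for f in fits], columns=terms)
    var = pd.DataFrame([(f.params["se"] ** 2).to_numpy() for f in fits], columns=terms)
    pooled = pool_rubin(est, var)
    if not spec.use_t:
        crit = stats.norm.ppf(0.975)
        pooled["ci_low"] = pooled["estimate"] - crit * pooled["se"]
        pooled["ci_high"] = pooled["estimate"] + crit * pooled["se"]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(pooled["se"] > 0, pooled["estimate"] / pooled["se"], np.inf)
        pooled["p"] = 2.0 * stats.norm.sf(np.abs(z))
    params = pooled[["estimate", "se", "ci_low", "ci_high", "p"]]
    diag = None
    if fits[0].diagnostics is not None:
        def _avg(attr: str) -> dict[str, float]:
            keys = getattr(fits[0].diagnostics, attr).keys()
            return {k: float(np.mean([getattr(f.diagnostics, attr)[k] for f in fits]))
                    for k in keys}
        diag = IvDiagnostics(f_stat=_avg("f_stat"), conditional_f=_avg("conditional_f"),
                             partial_r2=_avg("partial_r2"))
    return FitResult(params=params, n=fits[0].n, n_clusters=fits[0].n_clusters,
                     diagnostics=diag, dropped_columns=fits[0].dropped_columns)
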