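"""Synthetic trio-cohort generator.

Generates mother-father-child trios with Mendelian transmission of
haplotypes, an education phenotype driven by a polygenic score plus a
family-level confounder, optional phenotypic assortative mating, child
questionnaire outcomes with separate genetic-nurture (via parental
education) and direct-genetic (via the child's own score) paths, optional
per-variant horizontal pleiotropy, and configurable missingness in the
child outcomes.  Ground-truth parameters and realized latent quantities
are retained so downstream estimators can be validated against known
truth.

Causal structure
----------------
education_parent = mu + gamma * rawPGI_parent + conf_edu * C + noise
child outcome    = beta_m * edu_m + beta_f * edu_f + eta * stdPGI_child
                   + conf_outcome * C + sum_j alpha_j * g_child_j
                   + sex effect + noise

where C is a standard-normal family confounder shared by all members of a
trio and alpha_j ~ Normal(pleiotropy_mean, pleiotropy_sd^2) are direct
SNP-outcome effects that violate the exclusion restriction when nonzero.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "SimConfig",
    "TrioCohort",
    "simulate_snp_panel",
    "simulate_parents",
    "transmit_child",
    "build_phenotypes",
    "apply_missingness",
    "simulate_gwas_sumstats",
    "simulate_trio_cohort",
]

OUTCOME_RANGES_DEFAULT = {
    "smfq": (0.0, 26.0),
    "scared": (0.0, 10.0),
    "adhd_inattention": (0.0, 27.0),
    "adhd_hyperactivity": (0.0, 27.0),
    "adhd_total": (0.0, 54.0),
}

# Questionnaire score location/scale used only when discretizing latent
# outcomes onto bounded integer ranges (means/SDs of the emulated scales).
OUTCOME_SCORE_STATS = {
    "smfq": (1.9, 2.5),
    "scared": (1.0, 1.2),
    "adhd_inattention": (5.0, 4.1),
    "adhd_hyperactivity": (3.6, 3.9),
}

# Category probabilities for ordinal covariates (never / quit / current
# smoking; parity 0..4+), thresholded from latent normals loaded on C.
SMOKING_PROBS_MOTHER = (0.51, 0.42, 0.07)
SMOKING_PROBS_FATHER = (0.505, 0.208, 0.287)
PARITY_PROBS = (0.468, 0.357, 0.140, 0.027, 0.008)

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass
class SimConfig:
    """All knobs of the trio-cohort generator.

    ``gamma`` is the effect of the raw polygenic score on education in
    years per raw-score unit.  When ``None`` it is calibrated at
    simulation time so the score explains ``pgi_r2`` of education
    variance (default 1.4%, the regime of a strong but realistic
    education PGI).
    """

    n_families: int = 20_000
    n_snps: int = 200
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    ld_block_size: int = 10
    ld_adjacent_corr: float = 0.0
    weight_sd: float = 1.0
    gamma: float | None = None
    pgi_r2: float = 0.014
    edu_mean: float = 15.0
    edu_sd_noise: float = 2.3
    beta_mother: float = 0.0
    beta_father: float = 0.0
    eta: float = 0.0
    conf_edu: float = 0.0
    conf_outcome: float = 0.0
    am_rho: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    missing_rate_outcome: float = 0.0
    missing_mechanism: str = "MCAR"
    mar_edu_coef: float = -0.3
    discovery_n: float = 750_000.0
    discovery_pheno_sd: float = 2.4
    outcome_ranges: dict = field(default_factory=lambda: dict(OUTCOME_RANGES_DEFAULT))
    discretize_outcomes: bool = False
    outcome_noise_sd: float = 1.0
    sex_effect: float = 0.0
    conf_trait_loading: float = 0.5
    n_pcs: int = 20
    n_centers: int = 3
    n_chips: int = 2
    related_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"allele_freq_range must satisfy 0 < lo <= hi < 1, got {(lo, hi)}")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not (0.0 <= self.ld_adjacent_corr <= 1.0):
            raise ValueError("ld_adjacent_corr must be a probability")
        if not (0.0 <= self.am_rho < 1.0):
            raise ValueError("am_rho must be in [0, 1)")
        if not (0.0 <= self.missing_rate_outcome <= 1.0):
            raise ValueError("missing_rate_outcome must be in [0, 1]")
        if self.missing_mechanism not in ("MCAR", "MAR-on-education"):
            raise ValueError(f"unknown missing_mechanism {self.missing_mechanism!r}")
        for name, (mn, mx) in self.outcome_ranges.items():
            if not mn < mx:
                raise ValueError(f"outcome range for {name!r} must have min < max")
        if self.discovery_n <= 0:
            raise ValueError("discovery_n must be positive")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Parents:
    """Paired parental haplotypes and education phenotypes (couple i = row i)."""

    mother_haps: tuple[np.ndarray, np.ndarray]
    father_haps: tuple[np.ndarray, np.ndarray]
    edu_mother: np.ndarray
    edu_father: np.ndarray
    raw_pgi_mother: np.ndarray
    raw_pgi_father: np.ndarray
    confounder: np.ndarray
    gamma_used: float


@dataclass
class TrioCohort:
    """A simulated (or user-supplied) trio cohort.

    ``dosages`` maps role -> (n_families, n_snps) additive dosage array in
    row order matching ``phenotypes``.  ``truth`` holds the generating
    configuration and realized latent quantities; it is ``None`` for
    user-supplied data.
    """

    panel: pd.DataFrame
    dosages: dict[str, np.ndarray]
    phenotypes: pd.DataFrame
    truth: dict | None = None

    @property
    def n_families(self) -> int:
        return len(self.phenotypes)

    def dosage_frame(self) -> pd.DataFrame:
        """Long-wide dosage table: person_id, family_id, role, one column per variant."""
        ids = self.panel["snp_id"].tolist()
        frames = []
        fam = self.phenotypes["family_id"].to_numpy()
        for role in ("mother", "father", "child"):
            d = pd.DataFrame(self.dosages[role], columns=ids)
            d.insert(0, "role", role)
            d.insert(0, "family_id", fam)
            d.insert(0, "person_id", [f"{f}_{role}" for f in fam])
            frames.append(d)
        return pd.concat(frames, ignore_index=True)


def simulate_snp_panel(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the variant panel: ids, genomic coordinates, alleles, allele
    frequencies (uniform in ``allele_freq_range``) and true per-allele
    raw weights (zero-mean normal)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_snps
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
    weights = rng.normal(0.0, config.weight_sd, size=n)

    n_blocks = math.ceil(n / config.ld_block_size)
    block = np.arange(n) // config.ld_block_size
    # Blocks laid out so that row order is sorted by (chromosome, position):
    # consecutive blocks fill chromosome 1..22 in order, separated by more
    # than the default 10,000 kb clumping window.
    chrom = 1 + (22 * block) // max(n_blocks, 1)
    pos = np.empty(n, dtype=np.int64)
    within = np.arange(n) % config.ld_block_size
    block_rank = np.zeros(n, dtype=np.int64)
    for c in np.unique(chrom):
        m = chrom == c
        b = block[m]
        block_rank[m] = b - b.min()
    pos = block_rank * 20_000_000 + within * 10_000 + 1

    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(n)]
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(n)],
            "chrom": chrom.astype(int),
            "pos": pos,
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "freq": freqs,
            "true_weight": weights,
        }
    )


def _simulate_haplotypes(n_hap: int, panel: pd.DataFrame, config: SimConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Haplotypes under a within-block allele-copying Markov chain.

    Within an LD block the allele at locus j is a copy of the allele at
    locus j-1 with probability ``ld_adjacent_corr``, else a fresh
    Bernoulli(freq_j) draw; blocks are independent.
    """
    freqs = panel["freq"].to_numpy()
    L = len(freqs)
    c = config.ld_adjacent_corr
    H = np.empty((n_hap, L), dtype=np.int8)
    u = rng.random((n_hap, L))
    fresh = (u < freqs[None, :]).astype(np.int8)
    if c == 0.0:
        return fresh
    copy = rng.random((n_hap, L)) < c
    H[:, 0] = fresh[:, 0]
    for j in range(1, L):
        if j % config.ld_block_size == 0:
            H[:, j] = fresh[:, j]
        else:
            H[:, j] = np.where(copy[:, j], H[:, j - 1], fresh[:, j])
    return H


def _raw_pgi(dosages: np.ndarray, weights: np.ndarray) -> np.ndarray:
    return dosages.astype(np.float64) @ weights


def _calibrated_gamma(config: SimConfig, sd_raw: float) -> float:
    """gamma such that gamma*rawPGI explains ``pgi_r2`` of education variance."""
    r2 = config.pgi_r2
    resid_sd = math.hypot(config.conf_edu, config.edu_sd_noise)
    return math.sqrt(r2 / (1.0 - r2)) * resid_sd / sd_raw


def _pair_couples(edu_m: np.ndarray, edu_f: np.ndarray, config: SimConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Permutation p such that couple i = (mother i, father p[i]).

    Under assortative mating couples are rank-matched on education with
    additive matching noise whose SD is calibrated by bisection on a pilot
    pairing so the realized spousal education correlation (including the
    shared-confounder contribution added after pairing) approximates
    ``am_rho``.
    """
    n = len(edu_m)
    if config.am_rho == 0.0 or n < 3:
        return rng.permutation(n)
    sd = float(np.std(edu_m)) or 1.0
    pilot = np.random.default_rng(rng.integers(2**31))
    eps_m = pilot.normal(size=n)
    eps_f = pilot.normal(size=n)
    c_pilot = pilot.normal(size=n)

    def realized(log_tau: float) -> float:
        tau = 10.0**log_tau
        om = np.argsort(edu_m + tau * sd * eps_m)
        of = np.argsort(edu_f + tau * sd * eps_f)
        em = edu_m[om] + config.conf_edu * c_pilot
        ef = edu_f[of] + config.conf_edu * c_pilot
        return float(np.corrcoef(em, ef)[0, 1])

    lo, hi = -3.0, 3.0
    if realized(hi) >= config.am_rho:
        log_tau = hi
    elif realized(lo) <= config.am_rho:
        log_tau = lo
    else:
        log_tau = optimize.brentq(lambda t: realized(t) - config.am_rho, lo, hi, xtol=1e-3)
    tau = 10.0**log_tau
    om = np.argsort(edu_m + tau * sd * rng.normal(size=n))
    of = np.argsort(edu_f + tau * sd * rng.normal(size=n))
    # mother om[k] pairs with father of[k]; re-index to mother order
    p = np.empty(n, dtype=np.int64)
    p[om] = of
    return p


def simulate_parents(panel: pd.DataFrame, config: SimConfig,
                     rng: np.random.Generator) -> Parents:
    """Simulate parental haplotypes and education, and match couples."""
    if len(panel) == 0:
        raise ValueError("panel must be nonempty")
    n = config.n_families
    w = panel["true_weight"].to_numpy()
    H = _simulate_haplotypes(4 * n, panel, config, rng)
    mh1, mh2, fh1, fh2 = H[:n], H[n : 2 * n], H[2 * n : 3 * n], H[3 * n :]
    raw_m = _raw_pgi(mh1 + mh2, w)
    raw_f = _raw_pgi(fh1 + fh2, w)

    if config.gamma is not None:
        gamma = config.gamma
    else:
        sd_raw = float(np.std(np.concatenate([raw_m, raw_f])))
        gamma = _calibrated_gamma(config, sd_raw if sd_raw > 0 else 1.0)

    edu_m = config.edu_mean + gamma * raw_m + rng.normal(0.0, config.edu_sd_noise, n)
    edu_f = config.edu_mean + gamma * raw_f + rng.normal(0.0, config.edu_sd_noise, n)

    p = _pair_couples(edu_m, edu_f, config, rng)
    fh1, fh2, edu_f, raw_f = fh1[p], fh2[p], edu_f[p], raw_f[p]

    C = rng.normal(size=n)
    edu_m = edu_m + config.conf_edu * C
    edu_f = edu_f + config.conf_edu * C
    return Parents(
        mother_haps=(mh1, mh2),
        father_haps=(fh1, fh2),
        edu_mother=edu_m,
        edu_father=edu_f,
        raw_pgi_mother=raw_m,
        raw_pgi_father=raw_f,
        confounder=C,
        gamma_used=gamma,
    )


def transmit_child(mother_haps: tuple[np.ndarray, np.ndarray],
                   father_haps: tuple[np.ndarray, np.ndarray],
                   rng: np.random.Generator) -> np.ndarray:
    """Mendelian transmission: one uniformly chosen allele from each
    parent's pair at every locus, independently across loci."""
    mh1, mh2 = mother_haps
    fh1, fh2 = father_haps
    if mh1.shape != fh1.shape or mh1.shape != mh2.shape or fh1.shape != fh2.shape:
        raise ValueError("parental haplotype arrays must cover identical loci")
    from_m = np.where(rng.random(mh1.shape) < 0.5, mh1, mh2)
    from_f = np.where(rng.random(fh1.shape) < 0.5, fh1, fh2)
    return (from_m + from_f).astype(np.int8)


def _ordinal_from_latent(latent: np.ndarray, probs: tuple[float, ...]) -> np.ndarray:
    """Threshold a latent standard-normal-ish variable at the quantiles of
    ``probs`` (categories coded 0..len(probs)-1)."""
    z = (latent - latent.mean()) / (latent.std() or 1.0)
    cuts = stats.norm.ppf(np.cumsum(probs[:-1]))
    return np.digitize(z, cuts).astype(np.int64)


def build_phenotypes(parents: Parents, child_dosages: np.ndarray, panel: pd.DataFrame,
                     config: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Assemble the per-trio phenotype table and the ground-truth record."""
    n = config.n_families
    w = panel["true_weight"].to_numpy()
    raw_child = _raw_pgi(child_dosages, w)
    sd_raw_child = float(np.std(raw_child, ddof=1)) if n > 1 else 1.0
    std_child = (raw_child - raw_child.mean()) / (sd_raw_child or 1.0)

    C = parents.confounder
    sex = (rng.random(n) < 0.51).astype(np.int64)  # 1 = male
    birth_year = rng.integers(1998, 2010, size=n)

    alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=len(w)) \
        if (config.pleiotropy_mean != 0.0 or config.pleiotropy_sd != 0.0) else np.zeros(len(w))
    pleio = child_dosages.astype(np.float64) @ alpha

    structural = (
        config.beta_mother * parents.edu_mother
        + config.beta_father * parents.edu_father
        + config.eta * std_child
        + config.conf_outcome * C
        + pleio
        + config.sex_effect * sex
    )

    lam = config.conf_trait_loading
    res = math.sqrt(max(1.0 - lam**2, 0.0))

    def trait(mean: float, sd: float) -> np.ndarray:
        return mean + sd * (lam * C + res * rng.normal(size=n))

    pheno = pd.DataFrame({"family_id": np.arange(n, dtype=np.int64)})
    pheno["child_sex"] = sex
    pheno["birth_year"] = birth_year
    pheno["edu_mother_years"] = parents.edu_mother
    pheno["edu_father_years"] = parents.edu_father

    latents: dict[str, np.ndarray] = {}
    for name in ("smfq", "scared", "adhd_inattention", "adhd_hyperactivity"):
        share = 0.5 if name.startswith("adhd_") else 1.0
        latent = share * structural + rng.normal(0.0, config.outcome_noise_sd, n)
        latents[name] = latent
        if config.discretize_outcomes:
            mu, sd = OUTCOME_SCORE_STATS[name]
            mn, mx = config.outcome_ranges.get(name, OUTCOME_RANGES_DEFAULT[name])
            pheno[name] = np.clip(np.round(mu + sd * latent), mn, mx)
        else:
            pheno[name] = latent
    pheno["adhd_total"] = pheno["adhd_inattention"] + pheno["adhd_hyperactivity"]

    pheno["mother_depanx"] = trait(1.2, 1.9)
    pheno["father_depanx"] = trait(1.1, 2.1)
    pheno["mother_adhd"] = trait(6.7, 3.5)
    pheno["father_adhd"] = trait(8.2, 3.1)
    pheno["mother_smoking"] = _ordinal_from_latent(lam * C + res * rng.normal(size=n),
                                                   SMOKING_PROBS_MOTHER)
    pheno["father_smoking"] = _ordinal_from_latent(lam * C + res * rng.normal(size=n),
                                                   SMOKING_PROBS_FATHER)
    pheno["parity"] = _ordinal_from_latent(lam * C + res * rng.normal(size=n), PARITY_PROBS)
    pheno["batch_center"] = rng.integers(0, config.n_centers, size=n)
    pheno["batch_chip"] = rng.integers(0, config.n_chips, size=n)

    for role in ("mother", "father", "child"):
        for k in range(config.n_pcs):
            pheno[f"pc{k + 1}_{role}"] = rng.normal(size=n)

    # Genetic family clusters: a `related_fraction` of consecutive trio
    # pairs share a cluster (extended-family relatedness stand-in).
    cluster = np.arange(n, dtype=np.int64)
    if config.related_fraction > 0 and n > 1:
        merge = rng.random(n // 2) < config.related_fraction
        even = 2 * np.nonzero(merge)[0]
        cluster[even + 1] = cluster[even]
    pheno["family_cluster"] = cluster

    truth = {
        "config": dataclasses.asdict(config),
        "gamma_used": parents.gamma_used,
        "raw_pgi_mother": parents.raw_pgi_mother,
        "raw_pgi_father": parents.raw_pgi_father,
        "raw_pgi_child": raw_child,
        "std_pgi_child": std_child,
        "sd_raw_pgi_child": sd_raw_child,
        "confounder": C,
        "pleiotropy_alpha": alpha,
        "latent_outcomes": latents,
    }
    return pheno, truth


def apply_missingness(phenotypes: pd.DataFrame, config: SimConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Blank child outcome entries per the configured mechanism.

    MCAR: each outcome block independently missing at
    ``missing_rate_outcome``.  MAR-on-education: missingness probability is
    logistic in mean parental education with slope ``mar_edu_coef``, the
    intercept solved so the marginal rate matches.  The ADHD subscales and
    total share one mask (the total is a passive sum).  Genotypes are
    never made missing.
    """
    rate = config.missing_rate_outcome
    out = phenotypes.copy()
    if rate == 0.0:
        return out
    n = len(out)

    def mask_for(block_rng: np.random.Generator) -> np.ndarray:
        if config.missing_mechanism == "MCAR":
            return block_rng.random(n) < rate
        edu = 0.5 * (out["edu_mother_years"].to_numpy() + out["edu_father_years"].to_numpy())
        edu_c = edu - edu.mean()
        b = config.mar_edu_coef
        if rate >= 1.0:
            return np.ones(n, dtype=bool)

        def mean_rate(a: float) -> float:
            return float(special.expit(a + b * edu_c).mean()) - rate

        a = optimize.brentq(mean_rate, -40.0, 40.0)
        return block_rng.random(n) < special.expit(a + b * edu_c)

    for block in (["smfq"], ["scared"], ["adhd_inattention", "adhd_hyperactivity", "adhd_total"]):
        m = mask_for(rng)
        for col in block:
            out.loc[m, col] = np.nan
    return out


def simulate_gwas_sumstats(panel: pd.DataFrame, config: SimConfig,
                           rng: np.random.Generator, gamma: float = 1.0) -> pd.DataFrame:
    """Simulate discovery-GWAS summary statistics for the exposure.

    Published beta = gamma * true_weight + Normal(0, se^2), with per-variant
    se = pheno_sd / sqrt(2 f (1-f) N) (the standard continuous-trait
    per-allele sampling error).  ``discovery_n = inf`` gives the noiseless
    limit (se = 0).  ``gamma`` converts raw weights to the exposure
    (years-of-education) scale; the default 1.0 publishes raw weights.
    """
    f = panel["freq"].to_numpy()
    het = np.clip(2.0 * f * (1.0 - f), 1e-12, None)
    if math.isinf(config.discovery_n):
        se = np.zeros(len(panel))
    else:
        se = config.discovery_pheno_sd / np.sqrt(het * config.discovery_n)
    beta = gamma * panel["true_weight"].to_numpy() + np.where(se > 0, rng.normal(0.0, 1.0, len(panel)) * se, 0.0)
    pval = np.where(se > 0, 2.0 * stats.norm.sf(np.abs(beta) / np.where(se > 0, se, 1.0)),
                    np.where(beta == 0.0, 1.0, 0.0))
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {
            "snp_id": panel["snp_id"],
            "chrom": panel["chrom"],
            "pos": panel["pos"],
            "effect_allele": panel["effect_allele"],
            "other_allele": panel["other_allele"],
            "beta": beta,
            "se": np.where(se > 0, se, 0.0),
            "pvalue": pval,
            "eaf": f,
        }
    )


def simulate_trio_cohort(config: SimConfig,
                         rng: np.random.Generator | None = None) -> TrioCohort:
    """End-to-end cohort simulation: panel -> parents -> children -> phenotypes."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    panel = simulate_snp_panel(config, rng)
    parents = simulate_parents(panel, config, rng)
    child = transmit_child(parents.mother_haps, parents.father_haps, rng)
    pheno, truth = build_phenotypes(parents, child, panel, config, rng)
    pheno = apply_missingness(pheno, config, rng)
    dosages = {
        "mother": (parents.mother_haps[0] + parents.mother_haps[1]).astype(np.int8),
        "father": (parents.father_haps[0] + parents.father_haps[1]).astype(np.int8),
        "child": child,
    }
    return TrioCohort(panel=panel, dosages=dosages, phenotypes=pheno, truth=truth)
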