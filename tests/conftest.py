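import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from triomr import SimConfig, TrioCohort, simulate_trio_cohort

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort() -> TrioCohort:
    """A small but structured cohort: LD, assortment, confounding, and a
    planted direct genetic effect."""
    cfg = SimConfig(n_families=600, n_snps=40, seed=42, ld_adjacent_corr=0.4,
                    am_rho=0.3, eta=-0.1, conf_edu=0.3, conf_outcome=0.3,
                    n_pcs=2, related_fraction=0.2)
    return simulate_trio_cohort(cfg)


@pytest.fixture(scope="session")
def scored_cohort(small_cohort) -> TrioCohort:
    """Same cohort with true-weight polygenic scores merged into phenotypes."""
    cohort = small_cohort
    pheno = cohort.phenotypes.copy()
    w = cohort.panel["true_weight"].to_numpy()
    for role in ("mother", "father", "child"):
        raw = cohort.dosages[role].astype(float) @ w
        pheno[f"pgi_{role}"] = (raw - raw.mean()) / raw.std(ddof=1)
    return TrioCohort(panel=cohort.panel, dosages=cohort.dosages,
                      phenotypes=pheno, truth=cohort.truth)


def make_assocs(bx, by, se_x=None, se_y=None) -> pd.DataFrame:
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    se_x = np.zeros_like(bx) if se_x is None else np.asarray(se_x, dtype=float)
    se_y = np.ones_like(by) if se_y is None else np.asarray(se_y, dtype=float)
    return pd.DataFrame({"beta_exp": bx, "beta_out": by, "se_exp": se_x, "se_out": se_y})
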