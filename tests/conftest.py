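"""Shared simulated-cohort fixtures.

Everything is generated programmatically with fixed seeds; no data files.
"""

import numpy as np
import pandas as pd
import pytest

from adipomr.config import HazardShape, SimConfig
from adipomr.synth import (simulate_case_status, simulate_cohort,
                           simulate_exposures, simulate_genotypes)


@pytest.fixture(scope="session")
def linear_cohort():
    """20k cohort whose only exposure→hazard link is a linear WHR effect."""
    cfg = SimConfig(
        n_participants=20_000, n_variants=60, seed=11,
        missing_rate=0.0, extreme_bmi_rate=0.0,
        hazard_shape={"whr": HazardShape(kind="linear", slope=0.34)},
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def jshape_cohort():
    """20k cohort with a single quadratic BMI→hazard map (nadir 25)."""
    cfg = SimConfig(
        n_participants=20_000, n_variants=60, seed=13,
        missing_rate=0.0, extreme_bmi_rate=0.0,
        hazard_shape={"bmi": HazardShape(kind="quadratic", curvature=0.006,
                                         nadir=25.0)},
    )
    return simulate_cohort(cfg)


def case_control_table(n: int, seed: int, log_or: float, exposure: str = "bmi",
                       n_variants: int = 60, h2: float = 0.1):
    """Exposure table + genetic scores + binary case status with a known
    log-OR per SD; returns (table, score_series, dosages)."""
    cfg = SimConfig(n_participants=n, n_variants=n_variants, seed=seed,
                    prs_variance_explained=h2, missing_rate=0.0,
                    extreme_bmi_rate=0.0)
    dos = simulate_genotypes(n, n_variants, cfg.maf_range, seed)
    expo, scores, _ = simulate_exposures(dos, cfg)
    tab = expo.copy()
    tab.insert(0, "iid", tab.index)
    x = tab[exposure]
    x_sd = (x - x.mean()) / x.std(ddof=1)
    tab["case"] = simulate_case_status(x_sd, log_or, seed=seed)
    return tab, scores[exposure], dos


@pytest.fixture(scope="session")
def cc_table():
    """Case-control table with true OR 1.5/SD of BMI (n = 20k, R² = 0.1)."""
    return case_control_table(20_000, seed=17, log_or=np.log(1.5))


def random_summaries(rng: np.random.Generator, m: int) -> pd.DataFrame:
    """Random per-variant summary statistics for estimator oracles."""
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(m)],
        "beta_exp": rng.uniform(0.02, 0.3, m) * rng.choice([-1, 1], m),
        "se_exp": rng.uniform(0.005, 0.05, m),
        "beta_out": rng.normal(0, 0.1, m),
        "se_out": rng.uniform(0.01, 0.1, m),
    })
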