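"""Shared fixtures: small synthetic datasets reused across test modules."""

import warnings

import numpy as np
import pandas as pd
import pytest

from emovar.design import StudyDesign, SyntheticTruth
from emovar.preprocess import add_centered, align_lags
from emovar.synth import gen_index_level, gen_item_level


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    """Boundary variance components produce benign convergence chatter."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        warnings.filterwarnings("ignore", message=".*invalid value encountered.*")
        yield


@pytest.fixture(scope="session")
def two_designs():
    return [
        StudyDesign("dsA", 25, 10, 7, 4, 5, 5,
                    item_scale_min=1, item_scale_max=7,
                    age_mean=16.4, age_sd=0.7, prop_female=0.57),
        StudyDesign("dsB", 25, 5, 14, 2, 4, 6,
                    item_scale_min=0, item_scale_max=100,
                    age_mean=19.1, age_sd=1.3, prop_female=0.63),
    ]


@pytest.fixture(scope="session")
def item_records(two_designs):
    """Item-level records for two small studies (native scales)."""
    return gen_item_level(two_designs, seed=101)


@pytest.fixture(scope="session")
def analysis_table():
    """Index-level synthetic data, centered and lag-aligned, with truth."""
    truth = SyntheticTruth(seed=202, rho_ab=0.3)
    design = StudyDesign("sim", 150, 10, 7, 4, 5, 5, missing_rate=0.2)
    table, truth = gen_index_level(design, truth)
    table = table[~table["missing"]].copy()
    table = add_centered(table, ["ed", "erv", "intensity"])
    table = align_lags(table, ["ed_w", "ed"])
    return table, truth


def person_matrix(rng, t=40, k=4, icc_like=0.5):
    """Ad-hoc person item matrix with tunable item consistency."""
    f = rng.normal(size=t)
    lam = 1.0 + (1.0 - icc_like) * rng.normal(size=(t, k))
    x = 3.0 + lam * f[:, None] + (1.0 - icc_like + 0.3) * rng.normal(size=(t, k))
    return np.clip(x, 0, 10)
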