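"""Shared helpers for the mrscreen test suite."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrscreen.gwas_data import HarmonizedSet


def make_harmonized(bx, sx, by, sy, exposure_id="exp", outcome_id="out"):
    """Build a HarmonizedSet directly from effect arrays."""
    bx = np.asarray(bx, float)
    sx = np.asarray(sx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    j = len(bx)
    df = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(j)],
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "bx": bx, "sx": sx, "px": 2 * stats.norm.sf(np.abs(bx) / sx),
        "by": by, "sy": sy, "py": 2 * stats.norm.sf(np.abs(by) / sy),
    })
    return HarmonizedSet(exposure_id=exposure_id, outcome_id=outcome_id, df=df)


@pytest.fixture
def random_harmonized():
    """Factory for random harmonized sets with heterogeneous ratios."""

    def _make(j=10, seed=0, theta=0.3, noise=0.05):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
        sx = rng.uniform(0.005, 0.02, j)
        sy = rng.uniform(0.01, 0.05, j)
        by = theta * bx + noise * rng.standard_normal(j)
        return make_harmonized(bx, sx, by, sy)

    return _make
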