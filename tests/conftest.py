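"""Shared fixtures: one default synthetic cohort per session plus helpers."""

import numpy as np
import pandas as pd
import pytest

from microtype.core import FeatureTable
from microtype.synth import SynthConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (n=100, planted k=4, seed 42)."""
    return simulate_cohort(SynthConfig(rng_seed=42))


@pytest.fixture(scope="session")
def truth(cohort):
    return cohort["truth"]


def make_table(values, samples=None, features=None, level="otu", **kw):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"S{i}" for i in range(values.shape[0])]
    features = features or [f"F{j}" for j in range(values.shape[1])]
    return FeatureTable(pd.DataFrame(values, index=samples, columns=features), level=level, **kw)
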