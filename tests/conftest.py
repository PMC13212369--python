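"""Shared fixtures.

The anchored cohort and its fitted quantile models are expensive (14 linear
programs on 6000 points per sex), so they are built once per session and
shared by the growth-chart and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fhoc import GeneratorConfig, fit_quantile_curves, gen_cohort

#: Seed of the anchored study cohort used throughout the suite.
ANCHORED_SEED = 73


@pytest.fixture(scope="session")
def anchored_cohort() -> pd.DataFrame:
    """3000 children per sex (250 per age bin), anchored to the reference
    percentile table; bilateral, so 6000 hips per sex."""
    return gen_cohort(GeneratorConfig(n_per_sex_per_agegroup=250, seed=ANCHORED_SEED))


@pytest.fixture(scope="session")
def anchored_models(anchored_cohort):
    """Degree-3 monotone quantile models fitted to the anchored cohort."""
    return fit_quantile_curves(anchored_cohort, degree=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
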