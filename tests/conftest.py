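"""Shared fixtures: the default bank and a synthetic severity cohort.

The cohort fixture runs the full convolution pipeline once per session;
several tests (parameter recovery, monotone feature response) reuse it.
"""

from __future__ import annotations

import numpy as np
import pytest

import histoseverity as hs

COHORT_LEVELS = (0.0, 0.5, 1.0)
COHORT_N_PER_LEVEL = 20
COHORT_SEED = 20150915  # fixed study seed


@pytest.fixture(scope="session")
def bank():
    return hs.build_bank()


@pytest.fixture(scope="session")
def cohort(bank):
    """3 severity levels x 20 cutouts: cutouts, ground truth, feature matrix."""
    cutouts, truth = hs.generate_cohort(
        COHORT_N_PER_LEVEL, COHORT_LEVELS, seed=COHORT_SEED
    )
    matrix = hs.compute_feature_matrix(cutouts, bank=bank)
    return {"cutouts": cutouts, "truth": truth, "matrix": matrix}


@pytest.fixture(scope="session")
def fitted_cohort(cohort):
    """Severity model fitted on the session cohort, oriented by truth."""
    model = hs.SeverityModel(
        cohort["matrix"], labels=cohort["truth"]["severity"].to_numpy()
    )
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
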