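"""Shared fixtures; the expensive end-to-end simulations are session-scoped."""

import numpy as np
import pytest

from tiltmar.experiments import (
    run_dose_experiment,
    run_gammex_tilt_experiment,
    run_mar_comparison,
)

ACCEPTANCE_SEED = 0


@pytest.fixture(scope="session")
def gammex_result():
    """Six-position tilt-and-combine run of the titanium-rod disc."""
    return run_gammex_tilt_experiment(seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def dose_result():
    """Constant-total-dose run: 1x400 mAs vs 8 tilted scans at 50 mAs."""
    return run_dose_experiment(seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def mar_reports():
    """Ring reports for the uncorrected slice and the four MAR baselines."""
    return run_mar_comparison(seed=ACCEPTANCE_SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
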