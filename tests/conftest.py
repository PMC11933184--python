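import numpy as np
import pytest

from graftflow.model import simulate
from graftflow.parameters import build_default_parameters


@pytest.fixture(scope="session")
def default_params():
    return build_default_parameters()


@pytest.fixture(scope="session")
def default_run(default_params):
    """One converged 10-beat run at default parameters (shared, read-only)."""
    return simulate(default_params, n_beats=10)


@pytest.fixture(scope="session")
def stenosis_runs(default_params):
    """Runs at 0/50/75 % diameter reduction, all else default."""
    return {
        pct: simulate(default_params.replace(stenosis_pct=pct), n_beats=10)
        for pct in (0.0, 50.0, 75.0)
    }


@pytest.fixture(scope="session")
def small_cohort():
    from graftflow.synthclin import generate_cohort

    return generate_cohort(n_patients=8, grafts_per_patient=2, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
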