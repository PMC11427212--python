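import pytest

from rlsense.calibrate import optimize_metropolis_hastings, optimize_nelder_mead
from rlsense.synth import study_collapse_dataset


@pytest.fixture(scope="session")
def noiseless():
    """Noiseless study-grid collapse dataset with its ground truth."""
    return study_collapse_dataset(seed=7)


@pytest.fixture(scope="session")
def nm_scale_optima(noiseless):
    """Nelder-Mead optima from the three initial scales on the noiseless dataset."""
    data, _ = noiseless
    return [optimize_nelder_mead(data, s, s) for s in (10.0, 1.0, 0.1)]


@pytest.fixture(scope="session")
def mh_optimum(noiseless):
    """One long literal-rule Metropolis-Hastings run on the noiseless dataset."""
    data, _ = noiseless
    return optimize_metropolis_hastings(data, 10.0, 10.0, n_iter=10_000, seed=11)
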