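"""Shared fixtures: task geometry and small synthetic datasets.

Everything is generated programmatically with fixed seeds; no data
files are stored.
"""

import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

from pathint.ekf import TrialArrays
from pathint.params import IntegratorParams, ReportParams
from pathint.simulate import GenerativeAgent, simulate_participant
from pathint.task import make_paths, make_session_design


@pytest.fixture(scope="session")
def paths():
    return make_paths(seed=1)


@pytest.fixture(scope="session")
def design():
    return make_session_design(seed=2)


@pytest.fixture(scope="session")
def clean_agent():
    """A plausible agent without verbal bias (factors 1): leaky, gain
    slightly high, small bias, distance-accumulating noise, Weber
    reporting noise."""
    return GenerativeAgent(
        integrator=IntegratorParams(beta=0.05, alpha=1.1, bias=(0.05, -0.03),
                                    sigma0_sq=0.2),
        reporter=ReportParams(sigma_d_sq=0.0625, sigma_phi_sq=0.04))


@pytest.fixture(scope="session")
def small_dataset(paths, design, clean_agent):
    """One participant, one 48-trial session, tidy table + arrays."""
    trials, standard = simulate_participant(clean_agent, paths, design, rng=7)
    return trials, standard, TrialArrays.from_dataframe(trials)


@pytest.fixture(scope="session")
def cohort_errors(paths, design):
    """Small two-group cohort run through the error pipeline."""
    from pathint.errors import compute_errors
    from pathint.simulate import simulate_cohort
    trials, standard, _ = simulate_cohort(4, 3, design=design, paths=paths,
                                          seed=21)
    return compute_errors(trials, standard)


@pytest.fixture(scope="session")
def medium_arrays(paths, design, clean_agent):
    """One participant, 5 sessions (240 trials) for fitting tests."""
    trials, _ = simulate_participant(clean_agent, paths, design, rng=11,
                                     n_sessions=5)
    return TrialArrays.from_dataframe(trials)
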