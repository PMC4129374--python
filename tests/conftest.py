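import numpy as np
import pytest

import igtmodel as ig


@pytest.fixture(scope="session")
def schedule():
    """Canonical raw-currency payoff schedule."""
    return ig.build_schedule()


@pytest.fixture(scope="session")
def scaled_schedule(schedule):
    """Schedule on the modeling scale (divided by 100)."""
    return ig.scale_net_outcomes(schedule)


@pytest.fixture(scope="session")
def pvl_params():
    return ig.SubjectParameters(A=0.3, alpha=0.6, c=1.2, lam=1.8)


@pytest.fixture(scope="session")
def vpp_params():
    return ig.SubjectParameters(A=0.1, alpha=0.5, c=1.5, lam=0.8,
                                eps_p=0.2, eps_n=-0.6, k=0.4, w=0.7)


@pytest.fixture(scope="session")
def small_sequences(scaled_schedule, pvl_params):
    """Six simulated PVL-Delta subjects, 80 trials each."""
    rng = np.random.default_rng(42)
    out = []
    for i in range(6):
        p = ig.SubjectParameters(A=rng.uniform(0.05, 0.5),
                                 alpha=rng.uniform(0.2, 0.8),
                                 c=rng.uniform(0.5, 2.0),
                                 lam=rng.uniform(0.3, 2.5))
        out.append(ig.simulate_subject("pvl-delta", p, scaled_schedule,
                                       T=80, rng_seed=1000 + i))
    return out
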