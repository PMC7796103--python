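import numpy as np
import pytest

from surrokit.types import Endpoint, PseudoIPD


@pytest.fixture
def four_event_ipd():
    """n=4, one event at each of t=1..4: S-hat = 0.75, 0.5, 0.25, 0."""
    return PseudoIPD(
        arm_id="arm", endpoint=Endpoint.OS,
        times=np.array([1.0, 2.0, 3.0, 4.0]),
        events=np.ones(4, dtype=bool),
    )


@pytest.fixture
def step_ipd():
    """Step curve S-hat = 0.7 at t=3, 0.45 at t=7, 0.2 at t=12 (n=20)."""
    times = np.concatenate(
        [np.full(6, 3.0), np.full(5, 7.0), np.full(5, 12.0), np.full(4, 13.0)]
    )
    events = np.concatenate([np.ones(16, dtype=bool), np.zeros(4, dtype=bool)])
    return PseudoIPD(arm_id="arm", endpoint=Endpoint.OS, times=times, events=events)


def exponential_ipd(rate, n, seed, accrual=0.0, cutoff=None, arm_id="arm",
                    endpoint=Endpoint.OS):
    """Exponential event times with optional accrual/administrative censoring."""
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0 / rate, n)
    if cutoff is None:
        return PseudoIPD(arm_id=arm_id, endpoint=endpoint, times=t,
                         events=np.ones(n, dtype=bool))
    entry = rng.uniform(0.0, accrual, n) if accrual > 0 else np.zeros(n)
    cens = cutoff - entry
    return PseudoIPD(arm_id=arm_id, endpoint=endpoint,
                     times=np.minimum(t, cens), events=t <= cens)
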