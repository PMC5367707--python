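import numpy as np
import pytest

import burstlab as bl


@pytest.fixture(scope="session")
def small_population() -> bl.SimulatedPopulation:
    """A seeded population with planted supers and bots, reused across tests.

    Sized so that every non-bot user clears the 2000-edit eligibility bar
    over more than a year of activity: expected events per ordinary user are
    span_days * daily_initiations / (1 - continue_prob).
    """
    config = bl.GeneratorConfig(
        n_users=12, span_days=400, pareto_shape=2.0, xmin_minutes=1.0,
        cascade_continue_prob=0.6, bot_fraction=0.17, super_fraction=0.17,
        super_rate_factor=6.0, seed=11,
    )
    return bl.generate_population(config, bl.CircadianProfile.diurnal(scale=1.5))


@pytest.fixture()
def simple_stream() -> bl.EventStream:
    # three events an hour apart starting at 09:00 UTC
    base = 9 * 3600
    return bl.EventStream(
        user_id="u", times=np.array([base, base + 3600, base + 7200]),
        dataset_end=86_400,
    )
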