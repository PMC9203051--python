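import numpy as np
import pytest

from valencecode.config import five_odor_task
from valencecode.simulate import SimConfig, generate_population


@pytest.fixture(scope="session")
def small_population():
    """A small mixed-archetype session (one training day, block 1 only)."""
    sim = SimConfig(
        counts={
            "valence_coder": 3,
            "identity_coder": 2,
            "salience_coder": 1,
            "nonresponsive": 2,
        },
        session=five_odor_task(n_days=1),
    )
    return generate_population(sim, seed=11)


@pytest.fixture(scope="session")
def small_session(small_population):
    return small_population[0]


def noise_free_sim(counts, n_days=1, **kw):
    """Deterministic generator settings: no noise, drift, jitter, failures."""
    return SimConfig(
        counts=counts,
        session=five_odor_task(n_days=n_days),
        noise_sd=0.0,
        drift_sd=0.0,
        amp_jitter_sigma=0.0,
        reliability=1.0,
        inhibited_fraction=0.0,
        spontaneous_rate_per_frame=0.0,
        **kw,
    )
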