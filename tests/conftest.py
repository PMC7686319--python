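import numpy as np
import pytest

from longdti import SimulationConfig, generate_cohort
from longdti.simulate import default_trajectory_spec


def small_config(**kw) -> SimulationConfig:
    """Compact cohort: 4 tracts x 2 metrics, modest n; fast to analyze."""
    tracts = ("FMAJ", "FMIN", "lh.UNC", "rh.UNC")
    metrics = ("FA", "MD")
    defaults = dict(tracts=tracts, metrics=metrics, n_per_group=40, seed=11)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def noise_free_config(**kw) -> SimulationConfig:
    """All stochastic effects off: values lie exactly on the group curves."""
    metrics = kw.get("metrics", ("FA", "MD"))
    zero = {m: 0.0 for m in metrics}
    defaults = dict(
        tracts=("FMAJ", "FMIN", "lh.UNC", "rh.UNC"),
        metrics=metrics,
        n_per_group=40,
        random_intercept_sd=zero,
        residual_sd=zero,
        latent_effect=0.0,
        seed=11,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def noise_free_cohort():
    return generate_cohort(noise_free_config())


def planted_polynomial(cfg: SimulationConfig, tract: str, metric: str, age):
    """Evaluate the generating polynomial of one measure at given ages."""
    order, (b0, b1, b2) = cfg.trajectory_spec[(tract, metric)]
    age = np.asarray(age, dtype=float)
    out = np.full(age.shape, b0)
    if order >= 1:
        out = out + b1 * age
    if order >= 2:
        out = out + b2 * age * age
    return out
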