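import numpy as np
import pytest

from scramblefit import VesiclePopulation


@pytest.fixture(scope="session")
def population() -> VesiclePopulation:
    return VesiclePopulation()


def monte_carlo_p_at_least_one(
    alpha: float,
    x: float,
    n_vesicles: int,
    population: VesiclePopulation,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Independent occupancy oracle: sample Gaussian radii (truncated at 0,
    renormalized), Poisson counts with mean alpha*x*r^2/2, return the
    fraction of vesicles with count >= 1 and its binomial SE."""
    radii = rng.normal(population.mean_radius, population.sd_radius, n_vesicles)
    bad = radii <= 0
    while bad.any():
        radii[bad] = rng.normal(
            population.mean_radius, population.sd_radius, int(bad.sum())
        )
        bad = radii <= 0
    counts = rng.poisson(alpha * x * radii**2 / 2.0)
    p = float((counts >= 1).mean())
    se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_vesicles))
    return p, se
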