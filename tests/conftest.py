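"""Shared fixtures: deterministic synthetic lactations and populations."""

import numpy as np
import pytest

from resilmilk.data_io import LactationSeries
from resilmilk.synthetic_data import SimConfig, simulate_population


def make_wood_series(a=20.0, b=0.2, c=0.003, dims=None, noise_sd=0.0, seed=0,
                     animal_id="cow1"):
    """Noise-free (or iid-noise) series lying on a Wood curve."""
    if dims is None:
        dims = np.arange(1, 306)
    dims = np.asarray(dims)
    dmy = a * dims.astype(float) ** b * np.exp(-c * dims)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dmy = np.maximum(dmy + rng.normal(0.0, noise_sd, dims.size), 0.0)
    return LactationSeries(animal_id=animal_id, dims=dims, dmy=dmy)


def make_quartic_series(coeffs=(15.0, 0.25, -8e-4, 9e-7, -6e-10), dims=None,
                        animal_id="cow1"):
    """Series lying exactly on a quartic in raw DIM (clipped at 0)."""
    if dims is None:
        dims = np.arange(1, 306)
    dims = np.asarray(dims)
    dmy = np.maximum(np.polyval(np.asarray(coeffs)[::-1], dims.astype(float)), 0.0)
    return LactationSeries(animal_id=animal_id, dims=dims, dmy=dmy)


@pytest.fixture(scope="session")
def small_population():
    """A mixed-breed, mixed-herd population reused across tests (~350 cows)."""
    cfg = SimConfig(
        seed=2024,
        n_herds=6,
        cows_per_herd=(50, 70),
        herd_hol_mix=((0.4, 0.95, 1.0), (0.3, 0.3, 0.9), (0.3, 0.0, 0.5)),
    )
    return simulate_population(cfg)
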