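"""Shared fixtures: cached Monte Carlo sample sets and synthetic series."""

import numpy as np
import pytest

from shoalpol import monte_carlo as mc
from shoalpol import polarization, synthetic_data


@pytest.fixture(scope="session")
def mc_samples():
    """Session cache of null-model sample sets keyed by (N, n_samples, seed)."""
    cache = {}

    def get(N, n_samples=1_000_000, seed=1234):
        key = (N, n_samples, seed)
        if key not in cache:
            cache[key] = mc.sample_null(N, mc.McConfig(n_samples=n_samples, seed=seed))
        return cache[key]

    return get


def series_from_directions(ds, N=None, trial_id=""):
    """PolarizationSeries computed directly from a DirectionSet's headings.

    Bypasses the trajectory layer: every frame valid, dt = 1 s.
    """
    P = ds.polarization()
    T = P.size
    return polarization.PolarizationSeries(
        time=np.arange(T, dtype=float),
        P=P,
        P2=P * P,
        n_effective=np.full(T, ds.N),
        valid=np.ones(T, dtype=bool),
        meta={"N": N or ds.N, "trial_id": trial_id},
    )


@pytest.fixture()
def make_series():
    def build(N, T, regime, seed):
        ds = synthetic_data.draw_directions(N, T, regime, seed)
        return series_from_directions(ds)

    return build
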