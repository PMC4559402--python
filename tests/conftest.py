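"""Shared fixtures: reduced-scale configs and cached simulation runs.

The reduced test profile (200 thermometers, shorter runs) keeps the suite
fast; thermometer-count convergence is checked explicitly in the geometry
tests, and the acceptance tests widen tolerances accordingly.
"""

from __future__ import annotations

import numpy as np
import pytest

import huddlesim as hs


def make_config(variant, ambient, *, steps=4000, n_thermometers=200, seed=0, **thermal_kw):
    cfg = hs.SimConfig(
        variant=variant, steps=steps, n_thermometers=n_thermometers, seed=seed
    )
    cfg.thermal.ambient = float(ambient)
    for key, value in thermal_kw.items():
        setattr(cfg.thermal, key, value)
    return cfg


@pytest.fixture(scope="session")
def run_cache():
    """Memoised simulation runs shared across acceptance tests."""
    cache: dict = {}

    def get(variant, ambient, seed, *, steps=4000, n_thermometers=200, **thermal_kw):
        key = (variant, float(ambient), seed, steps, n_thermometers, tuple(sorted(thermal_kw.items())))
        if key not in cache:
            cfg = make_config(
                variant, ambient, steps=steps, n_thermometers=n_thermometers,
                seed=seed, **thermal_kw
            )
            cache[key] = hs.run_simulation(cfg, seed=seed)
        return cache[key]

    return get


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
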