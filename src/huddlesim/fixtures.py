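"""Deterministic hand-constructed litter configurations for tests and
debugging.  All pups have unit radius and 37 degC body temperature unless
noted; the arena radius is 10."""

from __future__ import annotations

import numpy as np

from .geometry import LitterState

__all__ = ["FIXTURE_NAMES", "fixture_litter"]

FIXTURE_NAMES = (
    "isolated",
    "touching_pair",
    "lens_pair_d_eq_r",
    "chain12",
    "two_clusters",
    "coincident_pair",
)


def _litter(positions, headings=None, temps=None, arena_radius=10.0) -> LitterState:
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return LitterState(
        positions=positions,
        headings=np.zeros(n) if headings is None else np.asarray(headings, float),
        body_temperatures=np.full(n, 37.0) if temps is None else np.asarray(temps, float),
        pup_radius=1.0,
        arena_radius=arena_radius,
    )


def fixture_litter(name: str) -> LitterState:
    """Build the named fixture case.

    isolated          one pup at the origin
    touching_pair     two pups at centre distance exactly 2r
    lens_pair_d_eq_r  two pups at centre distance r (analytic lens case:
                      each covers the fraction arccos(1/2)/pi = 1/3 of the
                      other's circumference)
    chain12           12 pups in a line at 1.5r spacing (one component)
    two_clusters      two tight groups of 6, cluster centres 10r apart
                      (arena enlarged so both fit)
    coincident_pair   two pups at the same point (degenerate d = 0 case)
    """
    if name == "isolated":
        return _litter([[0.0, 0.0]])
    if name == "touching_pair":
        return _litter([[0.0, 0.0], [2.0, 0.0]])
    if name == "lens_pair_d_eq_r":
        return _litter([[0.0, 0.0], [1.0, 0.0]])
    if name == "chain12":
        xs = 1.5 * np.arange(12)
        xs -= xs.mean()
        return _litter(np.column_stack((xs, np.zeros(12))))
    if name == "two_clusters":
        cluster = np.array(
            [[0.0, 0.0], [1.5, 0.0], [0.75, 1.3], [-1.5, 0.0], [-0.75, 1.3], [0.0, -1.5]]
        )
        left = cluster + [-5.0, 0.0]
        right = cluster + [5.0, 0.0]
        return _litter(np.vstack((left, right)), arena_radius=12.0)
    if name == "coincident_pair":
        return _litter([[0.0, 0.0], [0.0, 0.0]])
    raise ValueError(f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}")
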