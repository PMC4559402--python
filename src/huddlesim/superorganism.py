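"""Closed-form "super-organism" model of the whole litter.

Treating the litter as a single body that adapts its total exposed
surface area A to hold its temperature at the preferred value T_p (and
dropping the internal heat-exchange term, which cancels at the group
level), the steady state 0 = k1 * A * (T_a - T_b) + G with T_b = T_p
gives A = G / (k1 * (T_p - T_a)), clamped to the bounds [A_min, A_max]
measured from agent-based simulations:

    A(T_a) = A_min                      for T_a <= T_p - G/(k1 A_min)
           = A_max                      for T_a >= T_p - G/(k1 A_max)
           = G / (k1 (T_p - T_a))       otherwise,

    B(T_a) = T_a + G/(k1 A_min) | T_p | T_a + G/(k1 A_max)

on the same three branches.  The interior branch is the thermoregulatory
plateau: body temperature held at T_p over a band of ambient temperatures
of width (G/k1)(1/A_min - 1/A_max) centred on
T_p - (G/2k1)(1/A_min + 1/A_max).  The huddling prediction is 1 - A(T_a).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SuperOrganismParams",
    "exposed_area",
    "body_temperature",
    "plateau_range",
    "curve",
    "area_bounds_from_sweep",
]


@dataclass
class SuperOrganismParams:
    """G and k1 as in the agent model; A_min/A_max are the smallest and
    largest per-run mean exposed fractions measured over agent-based
    simulations (defaults are the canonical measured values)."""

    thermogenesis: float = 6.32
    k1: float = 1.0
    preferred_temperature: float = 37.0
    area_min: float = 0.36
    area_max: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.area_min <= self.area_max <= 1.0:
            raise ValueError("require 0 < area_min <= area_max <= 1")
        if self.thermogenesis < 0:
            raise ValueError("thermogenesis must be non-negative")
        if self.k1 <= 0:
            raise ValueError("k1 must be positive")


def _warn_if_degenerate(p: SuperOrganismParams) -> bool:
    if p.thermogenesis == 0.0:
        warnings.warn(
            "G = 0: the super-organism model degenerates to a sharp transition "
            "at the preferred temperature and is known not to match agent-based "
            "simulations there",
            stacklevel=3,
        )
        return True
    return False


def exposed_area(ambient, p: SuperOrganismParams):
    """Optimal exposed surface area A(T_a); huddling prediction is 1 - A."""
    ta = np.asarray(ambient, dtype=float)
    if _warn_if_degenerate(p):
        out = np.where(ta < p.preferred_temperature, p.area_min, p.area_max)
        return float(out) if out.ndim == 0 else out
    g, k1, tp = p.thermogenesis, p.k1, p.preferred_temperature
    interior = g / (k1 * (tp - np.where(ta < tp, ta, tp - 1.0)))  # guarded divide
    out = np.where(
        ta <= tp - g / (k1 * p.area_min),
        p.area_min,
        np.where(ta >= tp - g / (k1 * p.area_max), p.area_max, interior),
    )
    return float(out) if out.ndim == 0 else out


def body_temperature(ambient, p: SuperOrganismParams):
    """Settled group body temperature B(T_a); T_p on the plateau."""
    ta = np.asarray(ambient, dtype=float)
    if _warn_if_degenerate(p):
        # with G = 0 the body temperature tracks the ambient on all branches
        return float(ta) if ta.ndim == 0 else ta.copy()
    g, k1, tp = p.thermogenesis, p.k1, p.preferred_temperature
    out = np.where(
        ta <= tp - g / (k1 * p.area_min),
        ta + g / (k1 * p.area_min),
        np.where(ta >= tp - g / (k1 * p.area_max), ta + g / (k1 * p.area_max), tp),
    )
    return float(out) if out.ndim == 0 else out


def plateau_range(p: SuperOrganismParams) -> tuple[float, float]:
    """(width, centre) of the thermoregulatory plateau in ambient
    temperature: width = (G/k1)(1/A_min - 1/A_max), centre =
    T_p - (G/2k1)(1/A_min + 1/A_max).  Width grows with G and shrinks
    with k1 — the model's central testable prediction."""
    if p.thermogenesis <= 0:
        return 0.0, p.preferred_temperature
    g_over_k1 = p.thermogenesis / p.k1
    width = g_over_k1 * (1.0 / p.area_min - 1.0 / p.area_max)
    centre = p.preferred_temperature - 0.5 * g_over_k1 * (
        1.0 / p.area_min + 1.0 / p.area_max
    )
    return float(width), float(centre)


def curve(ambient_grid, p: SuperOrganismParams) -> pd.DataFrame:
    """Analytic curves tabulated over an ambient-temperature grid."""
    ta = np.asarray(ambient_grid, dtype=float)
    a = exposed_area(ta, p)
    return pd.DataFrame(
        {
            "ambient": ta,
            "exposed_area": a,
            "huddling": 1.0 - a,
            "body_temperature": body_temperature(ta, p),
        }
    )


def area_bounds_from_sweep(sweep: pd.DataFrame) -> tuple[float, float]:
    """(A_min, A_max) recomputed from a sweep table: the smallest and
    largest per-run mean exposed fraction (1 - huddling)."""
    exposed = 1.0 - sweep["huddling"].to_numpy(dtype=float)
    return float(exposed.min()), float(exposed.max())
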