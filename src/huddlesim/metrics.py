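"""Group-level observables of a simulation run.

huddling
    Mean over pups and recorded steps of (1 - eta), one minus the exposed
    thermometer fraction; 0 for a fully dispersed litter.
pup flow
    Mean over pups of the average absolute time derivative of eta,
    (1/(n_t - 1)) * sum_t |eta(t) - eta(t-1)| / dt, quantifying the
    continual exchange of positions between huddle centre and periphery
    (units 1/time; dt is the recording interval).
subgroups
    Connected components of the contact graph with an edge between pups
    whose centres are within 2r (touching or overlapping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import LitterState
from .trajectory import Trajectory

__all__ = [
    "SummaryMetrics",
    "huddling_metric",
    "pup_flow",
    "count_subgroups",
    "subgroup_timeseries",
    "mean_body_temperature",
    "summarize",
]


@dataclass
class SummaryMetrics:
    huddling: float
    mean_body_temperature: float
    pup_flow: float
    mean_subgroups: float
    mean_largest_aggregate: float
    max_aggregate_size: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def huddling_metric(traj: Trajectory) -> float:
    """Mean of (1 - eta) over pups and recorded steps."""
    if traj.n_steps < 1:
        raise ValueError("huddling metric requires at least one recorded step")
    return float(1.0 - traj.eta.mean())


def pup_flow(traj: Trajectory) -> float:
    """Mean over pups of the average absolute time derivative of eta.

    Consecutive recorded steps are used without smoothing; the recording
    interval is taken from the trajectory's time axis.
    """
    if traj.n_steps < 2:
        raise ValueError("pup flow requires at least two recorded steps")
    dt = float(traj.time[1] - traj.time[0])
    if dt <= 0:
        raise ValueError("trajectory time axis must be strictly increasing")
    return float(np.abs(np.diff(traj.eta, axis=0)).mean() / dt)


def _components(x: np.ndarray, y: np.ndarray, pup_radius: float):
    """(component count, largest component size) for one snapshot."""
    n = len(x)
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    adj = (dx * dx + dy * dy) <= (2.0 * pup_radius) ** 2
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    largest = int(np.bincount(labels).max())
    return n_comp, largest


def count_subgroups(litter: LitterState) -> int:
    """Number of connected contact-graph components (edges at d <= 2r)."""
    n_comp, _ = _components(
        litter.positions[:, 0], litter.positions[:, 1], litter.pup_radius
    )
    return int(n_comp)


def subgroup_timeseries(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-step component counts and largest component sizes."""
    counts = np.empty(traj.n_steps, dtype=int)
    largest = np.empty(traj.n_steps, dtype=int)
    for t in range(traj.n_steps):
        counts[t], largest[t] = _components(traj.x[t], traj.y[t], traj.pup_radius)
    return counts, largest


def mean_body_temperature(traj: Trajectory) -> float:
    """Mean body temperature over pups and recorded steps (degC)."""
    if traj.n_steps < 1:
        raise ValueError("mean body temperature requires at least one recorded step")
    return float(traj.body_temperature.mean())


def summarize(traj: Trajectory) -> SummaryMetrics:
    """All summary metrics of one trajectory (NaNs for an empty one)."""
    if traj.n_steps == 0:
        nan = float("nan")
        return SummaryMetrics(nan, nan, nan, nan, nan, 0)
    counts, largest = subgroup_timeseries(traj)
    return SummaryMetrics(
        huddling=huddling_metric(traj),
        mean_body_temperature=mean_body_temperature(traj),
        pup_flow=pup_flow(traj) if traj.n_steps >= 2 else 0.0,
        mean_subgroups=float(counts.mean()) if len(counts) else float("nan"),
        mean_largest_aggregate=float(largest.mean()) if len(largest) else float("nan"),
        max_aggregate_size=int(largest.max()) if len(largest) else 0,
    )
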