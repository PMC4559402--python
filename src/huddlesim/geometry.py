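"""Pup geometry: thermometer placement, contact detection, exposure fields.

Each pup is a circle of radius ``r`` carrying ``n`` thermometers evenly
spaced around its circumference.  A thermometer of pup *i* is "contacted"
when it falls inside the body of a littermate *j*; the published criterion
compares the angular offset of the thermometer from the bearing of *j*
against the half-angle ``arccos(d_ij / 2r)`` of the contact lens.  For
equal radii this is algebraically identical to the Euclidean test
"thermometer lies within distance r of the centre of j", which is what the
vectorised field computation uses (the angular form is kept in
:func:`contact_indicator` and the equivalence is property-tested).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PupState",
    "LitterState",
    "ContactField",
    "thermometer_offsets",
    "thermometer_positions",
    "circular_distance",
    "contact_indicator",
    "compute_contact_field",
]


@dataclass
class PupState:
    """State of a single pup: centre, heading, body temperature, radius."""

    x: float
    y: float
    heading: float
    body_temperature: float
    radius: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("pup radius must be positive")
        if not np.isfinite(self.heading):
            raise ValueError("pup heading must be finite")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class LitterState:
    """Whole-litter snapshot as flat arrays (one row per pup).

    Headings follow the counterclockwise-positive mathematical convention
    and are stored unwrapped (nothing downstream depends on wrapping).
    """

    positions: np.ndarray  # (N, 2)
    headings: np.ndarray  # (N,)
    body_temperatures: np.ndarray  # (N,)
    pup_radius: float = 1.0
    arena_radius: float = 10.0
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.headings = np.asarray(self.headings, dtype=float)
        self.body_temperatures = np.asarray(self.body_temperatures, dtype=float)
        if self.pup_radius <= 0:
            raise ValueError("pup radius must be positive")

    @property
    def n_pups(self) -> int:
        return len(self.positions)

    def pup(self, i: int) -> PupState:
        return PupState(
            x=self.positions[i, 0],
            y=self.positions[i, 1],
            heading=self.headings[i],
            body_temperature=self.body_temperatures[i],
            radius=self.pup_radius,
        )

    def copy(self) -> "LitterState":
        return replace(
            self,
            positions=self.positions.copy(),
            headings=self.headings.copy(),
            body_temperatures=self.body_temperatures.copy(),
        )


@dataclass
class ContactField:
    """Per-thermometer contact state for one litter snapshot.

    ``epsilon[i, k]`` is 1 where thermometer k of pup i is exposed to the
    ambient air, ``eta[i]`` the exposed fraction, ``chi[i, k]`` the body
    temperature of the nearest contacting littermate (0 where exposed),
    ``nearest[i, k]`` that littermate's index (−1 where exposed) and
    ``contact_temperature[i]`` the mean of chi over contacted thermometers
    (reported as the pup's own body temperature for fully isolated pups so
    the heat-exchange term vanishes exactly).
    """

    epsilon: np.ndarray  # (N, n) bool
    eta: np.ndarray  # (N,)
    chi: np.ndarray  # (N, n)
    nearest: np.ndarray  # (N, n) int
    contact_temperature: np.ndarray  # (N,)

    @property
    def n_thermometers(self) -> int:
        return self.epsilon.shape[1]


def thermometer_offsets(n: int) -> np.ndarray:
    """Angular offsets (k − 1/2)·2π/n, k = 1..n, from the pup's heading.

    The first n/2 offsets lie in (0, π): those thermometers sit on the
    pup's left; the second half sit on its right.  ``n`` must be even so
    the left/right split is defined.
    """
    if n < 2 or n % 2 != 0:
        raise ValueError(f"thermometer count must be even and >= 2, got {n}")
    return (np.arange(n) + 0.5) * (2.0 * np.pi / n)


def thermometer_positions(pup: PupState, n: int) -> np.ndarray:
    """Coordinates of the n thermometers of ``pup``, shape (n, 2)."""
    angles = pup.heading + thermometer_offsets(n)
    return np.column_stack(
        (pup.x + pup.radius * np.cos(angles), pup.y + pup.radius * np.sin(angles))
    )


def circular_distance(a) -> np.ndarray:
    """Absolute distance around the circle: [a] = π − |π − |a mod 2π||."""
    a = np.abs(np.asarray(a, dtype=float)) % (2.0 * np.pi)
    return np.pi - np.abs(np.pi - a)


def contact_indicator(pup_i: PupState, pup_j: PupState, k, n: int):
    """Angular contact test: does thermometer k of pup i fall inside pup j?

    Returns 1 where the centre distance d satisfies d < 2r and the
    circular distance between the thermometer bearing and the bearing of
    pup j is below the lens half-angle arccos(d / 2r).  ``k`` may be a
    scalar or an integer array (0-based).  Coincident centres (d = 0)
    leave the bearing undefined and are rejected; the simulation treats
    that degenerate case as full overlap (see the collision handling in
    :mod:`huddlesim.behaviour`).
    """
    k = np.asarray(k)
    dx = pup_j.x - pup_i.x
    dy = pup_j.y - pup_i.y
    d = float(np.hypot(dx, dy))
    if d == 0.0:
        raise ValueError("contact_indicator undefined for coincident centres")
    r = pup_i.radius
    if d >= 2.0 * r:
        return np.zeros(k.shape, dtype=int) if k.ndim else 0
    phi = np.arctan2(dy, dx)
    therm_angle = pup_i.heading + thermometer_offsets(n)[k]
    half_angle = np.arccos(d / (2.0 * r))
    out = (circular_distance(therm_angle - phi) < half_angle).astype(int)
    return out if k.ndim else int(out)


def compute_contact_field(litter: LitterState, n: int) -> ContactField:
    """Contact indicators, exposure flags and contact temperatures.

    Vectorised over pups and thermometers.  A thermometer is contacted iff
    it lies within distance r (closed disc, so that coincident centres
    count as full overlap) of some littermate centre; the
    registered temperature is the body temperature of the littermate whose
    centre is nearest (ties broken by lowest pup index, the behaviour of
    ``argmin`` on equal values).
    """
    if litter.n_pups < 1:
        raise ValueError("litter must contain at least one pup")
    r = litter.pup_radius
    npup = litter.n_pups
    tb = litter.body_temperatures

    angles = litter.headings[:, None] + thermometer_offsets(n)[None, :]
    tx = litter.positions[:, 0, None] + r * np.cos(angles)  # (N, n)
    ty = litter.positions[:, 1, None] + r * np.sin(angles)

    if npup == 1:
        epsilon = np.ones((1, n), dtype=bool)
        return ContactField(
            epsilon=epsilon,
            eta=np.ones(1),
            chi=np.zeros((1, n)),
            nearest=np.full((1, n), -1, dtype=np.int64),
            contact_temperature=tb.copy(),
        )

    dx = tx[:, :, None] - litter.positions[None, None, :, 0]  # (N, n, N)
    dy = ty[:, :, None] - litter.positions[None, None, :, 1]
    dist2 = dx * dx + dy * dy
    idx = np.arange(npup)
    dist2[idx, :, idx] = np.inf  # a pup never contacts itself

    nearest = np.argmin(dist2, axis=2)  # (N, n)
    min_dist2 = np.take_along_axis(dist2, nearest[:, :, None], axis=2)[:, :, 0]
    # tiny relative tolerance so exact-boundary cases (coincident centres
    # place every thermometer at distance exactly r) register as contact
    contacted = min_dist2 <= r * r * (1.0 + 1e-12)
    epsilon = ~contacted
    eta = epsilon.mean(axis=1)

    chi = np.where(contacted, tb[nearest], 0.0)
    n_contacted = contacted.sum(axis=1)
    with np.errstate(invalid="ignore"):
        tc = np.where(n_contacted > 0, chi.sum(axis=1) / np.maximum(n_contacted, 1), tb)
    return ContactField(
        epsilon=epsilon,
        eta=eta,
        chi=chi,
        nearest=np.where(contacted, nearest, -1),
        contact_temperature=tc,
    )
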