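"""Sensor-to-motor mapping and kinematics (Braitenberg-style thermotaxis).

The left/right surface temperatures drive the contralateral motors,

    M_L = F(T_R) / (F(T_L) + F(T_R)),   M_R = F(T_L) / (F(T_L) + F(T_R)),

so M_L + M_R = 1 by construction.  F is the identity for the endothermic
and ectothermic variants; the homeothermotaxic variant uses the sigmoid

    F(T) = 1 / (1 + exp(-(T_p - T_b) * T / sigma)),

whose slope in T changes sign with the sign of (T_p - T_b): a pup colder
than its preferred temperature T_p seeks warmth, a warmer pup avoids it.

A pup turns toward the side whose sensor drives the larger contralateral
motor.  In the counterclockwise-positive coordinate frame used throughout
(translation along (cos theta, sin theta), first half of the thermometers
on the left) this reads

    theta <- theta + dt * arctan(v1 * (M_R - M_L)),

so a warmer right side (M_L > M_R) yields a clockwise turn toward the
warmth.  Translation adds a constant forward speed v2, an inward radial
spring when a pup breaches the circular arena wall, and a pairwise
repulsion spring of magnitude (r - d/2) between overlapping pups.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .geometry import LitterState

__all__ = [
    "Variant",
    "KinematicParams",
    "MotorDrives",
    "transfer",
    "motor_speeds",
    "heading_increment",
    "position_step",
]


class Variant(str, enum.Enum):
    """The three model variants.

    endothermic
        Body temperature clamped at 37 degC; identity transfer.
    ectothermic
        Dynamic body temperature; identity transfer (pure heat seeking).
    homeothermotaxic
        Dynamic body temperature; sigmoidal transfer gated by the
        discrepancy between body and preferred temperature.
    """

    ENDOTHERMIC = "endothermic"
    ECTOTHERMIC = "ectothermic"
    HOMEOTHERMOTAXIC = "homeothermotaxic"

    def __str__(self) -> str:  # yaml/click friendliness
        return self.value


@dataclass
class KinematicParams:
    """Behavioural constants.

    v1 : rotation gain (unitless); v2 : forward speed (pup radii/time);
    preferred_temperature : T_p (degC); sigma : transfer-function
    steepness (degC^2).
    """

    v1: float = 200.0
    v2: float = 0.3
    preferred_temperature: float = 37.0
    sigma: float = 100.0

    def __post_init__(self) -> None:
        if self.v1 <= 0 or self.v2 <= 0:
            raise ValueError("v1 and v2 must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class MotorDrives:
    """Normalised motor speeds, M_L + M_R = 1 exactly."""

    left: np.ndarray
    right: np.ndarray


def transfer(temperature, body_temperature, params: KinematicParams, variant: Variant):
    """Sensor transfer function F.

    Identity for all but the homeothermotaxic variant, for which
    F(T) = (1 + exp(-(T_p - T_b) T / sigma))^-1: increasing in T when the
    pup is colder than T_p, decreasing when warmer, and exactly 1/2
    everywhere when T_b = T_p.
    """
    t = np.asarray(temperature, dtype=float)
    if Variant(variant) is not Variant.HOMEOTHERMOTAXIC:
        return t
    tb = np.asarray(body_temperature, dtype=float)
    z = (params.preferred_temperature - tb) * t / params.sigma
    return 1.0 / (1.0 + np.exp(-z))


def motor_speeds(f_left, f_right) -> MotorDrives:
    """Contralateral normalised drives from the transferred sensor values.

    Where F(T_L) + F(T_R) = 0 (possible only for identity transfer at zero
    temperatures) both motors are set to 1/2, continuing the symmetric
    case.
    """
    fl = np.asarray(f_left, dtype=float)
    fr = np.asarray(f_right, dtype=float)
    total = fl + fr
    safe = np.where(total == 0.0, 1.0, total)
    left = np.where(total == 0.0, 0.5, fr / safe)
    right = 1.0 - left  # exact complement: M_L + M_R = 1 by construction
    return MotorDrives(left=left, right=right)


def heading_increment(drives: MotorDrives, params: KinematicParams, dt: float):
    """Heading change dt * arctan(v1 (M_R - M_L)), toward the stronger
    contralateral drive; magnitude bounded by dt * pi/2."""
    return dt * np.arctan(params.v1 * (drives.right - drives.left))


def position_step(
    litter: LitterState,
    params: KinematicParams,
    dt: float,
    boundary_enabled: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """New positions after forward motion, boundary and collision forces.

    All forces are evaluated on the supplied (start-of-step) state.  The
    boundary spring beta = r_arena - |x| - r engages only when the pup
    breaches the wall (|x| + r >= r_arena) and is then non-positive,
    pushing inward.  Overlapping pups repel each other along the line of
    centres with magnitude (r - d/2); coincident centres (d = 0) take a
    random push direction drawn from ``rng``.
    """
    x = litter.positions
    r = litter.pup_radius
    n = litter.n_pups

    velocity = params.v2 * np.column_stack(
        (np.cos(litter.headings), np.sin(litter.headings))
    )

    if boundary_enabled:
        norm = np.linalg.norm(x, axis=1)
        breach = norm + r >= litter.arena_radius
        beta = np.where(breach, litter.arena_radius - norm - r, 0.0)
        radial = np.divide(
            x, norm[:, None], out=np.zeros_like(x), where=norm[:, None] > 0
        )
        velocity = velocity + beta[:, None] * radial

    if n > 1:
        diff = x[:, None, :] - x[None, :, :]  # points from j toward i
        d = np.linalg.norm(diff, axis=2)
        overlap = (d <= 2.0 * r) & ~np.eye(n, dtype=bool)
        magnitude = np.where(overlap, r - d / 2.0, 0.0)
        coincident = overlap & (d == 0.0)
        if coincident.any():
            if rng is None:
                raise ValueError("coincident pups require an rng for the push direction")
            ang = rng.uniform(0.0, 2.0 * np.pi, size=int(coincident.sum()))
            diff[coincident] = np.column_stack((np.cos(ang), np.sin(ang)))
            d = np.where(coincident, 1.0, d)
        unit = np.divide(diff, d[:, :, None], out=np.zeros_like(diff), where=d[:, :, None] > 0)
        velocity = velocity + (magnitude[:, :, None] * unit).sum(axis=1)

    return x + dt * velocity
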