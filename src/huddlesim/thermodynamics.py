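"""Surface and body-temperature dynamics.

The body temperature of pup i evolves by forward Euler on

    dTb/dt = -k1 * eta * (Tb - Ta) - k2 * (1 - eta) * (Tb - Tc) + G

where ``eta`` is the exposed surface fraction, ``Tc`` the mean body
temperature registered over contacted thermometers, ``k1``/``k2`` the
thermal conductances of exposed/contact surface, ``G`` the constant rate
of (brown-adipose-tissue) thermogenesis and ``Ta`` the ambient
temperature.  An isolated pup (eta = 1) relaxes exponentially to
``Ta + G/k1``, which recovers the standard endothermic metabolic relation
G = k1 * eta * (Tb - Ta) at steady state.

Conductances are expressed per unit time with the pup circumference as the
unit of contour length (2*pi*r = 1), giving the defaults k1 = 1, k2 = 2.5.

The *endothermic* model variant bypasses the equation entirely and holds
every body temperature at 37 degC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ContactField

__all__ = [
    "ThermalParams",
    "SurfaceTemperatures",
    "surface_temperatures",
    "contact_mean_temperature",
    "body_temperature_step",
    "ENDOTHERMIC_BODY_TEMPERATURE",
]

#: Body temperature (degC) clamped by the endothermic variant.
ENDOTHERMIC_BODY_TEMPERATURE = 37.0


@dataclass
class ThermalParams:
    """Thermal constants.

    k1, k2
        Conductances (1/time) for exposed and contact surface.
    thermogenesis
        Constant internal heat production G (degC/time).
    ambient
        Ambient temperature Ta (degC).
    contact_scaling
        Fraction s in (0, 1] of a contacting littermate's body temperature
        registered by a thermometer (sensing only; the heat-exchange term
        of the body-temperature equation is not scaled).  Lowers the
        endothermic critical temperature to s*37 degC.
    sensor_noise_variance
        Variance (degC^2) of i.i.d. zero-mean Gaussian noise added to each
        thermometer reading at each timestep; 0 disables noise.
    dt
        Integration timestep (time units).
    """

    k1: float = 1.0
    k2: float = 2.5
    thermogenesis: float = 6.32
    ambient: float = 20.0
    contact_scaling: float = 1.0
    sensor_noise_variance: float = 0.0
    dt: float = 0.05

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("thermal conductances k1, k2 must be positive")
        if self.dt <= 0:
            raise ValueError("timestep dt must be positive")
        if not 0.0 < self.contact_scaling <= 1.0:
            raise ValueError("contact_scaling must lie in (0, 1]")
        if self.sensor_noise_variance < 0:
            raise ValueError("sensor_noise_variance must be non-negative")


@dataclass
class SurfaceTemperatures:
    """Per-thermometer temperatures and the left/right sensor values."""

    tau: np.ndarray  # (N, n)
    left: np.ndarray  # (N,) mean over the first n/2 thermometers
    right: np.ndarray  # (N,) mean over the second n/2


def surface_temperatures(
    field: ContactField,
    params: ThermalParams,
    rng: np.random.Generator | None = None,
) -> SurfaceTemperatures:
    """Thermometer readings tau = Ta*epsilon + s*chi (+ optional noise).

    The left (right) sensor value is the mean of tau over the first
    (second) half of the thermometers, which tile the left (right) body
    half.  Noise draws, when enabled, are fresh per thermometer per call.
    """
    tau = params.ambient * field.epsilon + params.contact_scaling * field.chi
    if params.sensor_noise_variance > 0.0:
        if rng is None:
            raise ValueError("sensor noise enabled but no rng supplied")
        tau = tau + rng.normal(
            0.0, np.sqrt(params.sensor_noise_variance), size=tau.shape
        )
    half = field.n_thermometers // 2
    return SurfaceTemperatures(
        tau=tau, left=tau[:, :half].mean(axis=1), right=tau[:, half:].mean(axis=1)
    )


def contact_mean_temperature(
    field: ContactField, body_temperatures: np.ndarray | None = None
) -> np.ndarray:
    """Contact-mediated surface temperature Tc per pup.

    Mean of chi over contacted thermometers; for a fully isolated pup the
    pup's own body temperature is reported (when supplied) so that the
    exchange term -k2*(1-eta)*(Tb - Tc) is exactly zero.
    """
    contacted = ~field.epsilon
    counts = contacted.sum(axis=1)
    sums = np.where(contacted, field.chi, 0.0).sum(axis=1)
    mean = sums / np.maximum(counts, 1)
    if body_temperatures is not None:
        return np.where(counts > 0, mean, body_temperatures)
    return np.where(counts > 0, mean, np.nan)


def body_temperature_step(
    body_temperature: np.ndarray,
    eta: np.ndarray,
    contact_temperature: np.ndarray,
    params: ThermalParams,
    variant: str = "ectothermic",
) -> np.ndarray:
    """One forward-Euler update of the body temperature(s).

    The endothermic variant returns 37 degC unconditionally; the other
    variants integrate heat decay, heat exchange and thermogenesis.
    """
    tb = np.asarray(body_temperature, dtype=float)
    if getattr(variant, "value", variant) == "endothermic":
        return np.full_like(tb, ENDOTHERMIC_BODY_TEMPERATURE)
    eta = np.asarray(eta, dtype=float)
    tc = np.asarray(contact_temperature, dtype=float)
    dtb = (
        -params.k1 * eta * (tb - params.ambient)
        - params.k2 * (1.0 - eta) * (tb - tc)
        + params.thermogenesis
    )
    return tb + params.dt * dtb
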