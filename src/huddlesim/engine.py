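"""Initialisation, settle phase, main loop and experiment protocols.

Each timestep applies, synchronously for all pups from the start-of-step
state: (i) thermometer readings and left/right sensor values, (ii) motor
speeds, (iii) heading update, (iv) translation with boundary and
collision forces, (v) body-temperature update.  Pups start piled within
one pup radius of the arena centre (a pre-formed macro-huddle) at 30 degC
and the temperatures settle for ``settle_steps`` before kinematics are
enabled; settle records are excluded from the trajectory and from every
metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .behaviour import (
    Variant,
    heading_increment,
    motor_speeds,
    position_step,
    transfer,
)
from .config import SimConfig
from .geometry import LitterState, compute_contact_field
from .thermodynamics import (
    ENDOTHERMIC_BODY_TEMPERATURE,
    body_temperature_step,
    surface_temperatures,
)
from .trajectory import Trajectory

__all__ = [
    "initialize_litter",
    "settle",
    "step",
    "run_simulation",
    "run_sweep",
    "summarize_sweep",
    "SimulationResult",
    "SWEEPABLE_PARAMS",
]

#: ThermalParams fields that run_sweep may vary.
SWEEPABLE_PARAMS = ("ambient", "thermogenesis", "contact_scaling", "sensor_noise_variance")


@dataclass
class SimulationResult:
    trajectory: Trajectory
    final_state: LitterState
    summary: "metrics_mod.SummaryMetrics"
    config: SimConfig
    seed: int


def initialize_litter(config: SimConfig, rng: np.random.Generator) -> LitterState:
    """Pups i.i.d. uniform in the disc of one pup radius about the arena
    centre, headings uniform on [0, 2pi), body temperatures at the initial
    value (37 degC for the endothermic variant, whose temperature is
    clamped)."""
    n = config.n_pups
    radius = config.pup_radius * np.sqrt(rng.uniform(size=n))
    angle = rng.uniform(0.0, 2.0 * np.pi, size=n)
    positions = np.column_stack((radius * np.cos(angle), radius * np.sin(angle)))
    headings = rng.uniform(0.0, 2.0 * np.pi, size=n)
    if config.variant is Variant.ENDOTHERMIC:
        tb = np.full(n, ENDOTHERMIC_BODY_TEMPERATURE)
    else:
        tb = np.full(n, float(config.initial_body_temperature))
    return LitterState(
        positions=positions,
        headings=headings,
        body_temperatures=tb,
        pup_radius=config.pup_radius,
        arena_radius=config.arena_radius,
        time=0.0,
    )


def settle(litter: LitterState, config: SimConfig) -> LitterState:
    """Apply ``settle_steps`` body-temperature updates with positions and
    headings frozen.  A no-op for the endothermic variant."""
    if config.variant is Variant.ENDOTHERMIC:
        return litter
    for _ in range(config.settle_steps):
        fld = compute_contact_field(litter, config.n_thermometers)
        litter.body_temperatures = body_temperature_step(
            litter.body_temperatures,
            fld.eta,
            fld.contact_temperature,
            config.thermal,
            config.variant,
        )
    return litter


def step(litter: LitterState, config: SimConfig, rng: np.random.Generator):
    """Advance the litter by one timestep (in place).

    Returns the litter and the start-of-step contact field (whose eta is
    the exposure the trajectory records for this step).
    """
    fld = compute_contact_field(litter, config.n_thermometers)
    surface = surface_temperatures(fld, config.thermal, rng)
    tb = litter.body_temperatures
    drives = motor_speeds(
        transfer(surface.left, tb, config.kinematic, config.variant),
        transfer(surface.right, tb, config.kinematic, config.variant),
    )
    dt = config.thermal.dt
    new_headings = litter.headings + heading_increment(drives, config.kinematic, dt)
    new_positions = position_step(
        litter, config.kinematic, dt, config.boundary_enabled, rng
    )
    new_tb = body_temperature_step(
        tb, fld.eta, fld.contact_temperature, config.thermal, config.variant
    )
    litter.headings = new_headings
    litter.positions = new_positions
    litter.body_temperatures = new_tb
    litter.time += dt
    return litter, fld


def run_simulation(config: SimConfig, seed: int | None = None) -> SimulationResult:
    """Initialise, settle, then iterate ``config.steps`` timesteps.

    The trajectory stores one record per step: the pre-update state and
    the exposed fractions sensed at that step.  A non-finite state aborts
    with a diagnostic (the usual cause is an oversized dt).
    """
    used_seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(used_seed)
    litter = settle(initialize_litter(config, rng), config)

    s, n = config.steps, config.n_pups
    rec = {
        name: np.empty((s, n))
        for name in ("x", "y", "heading", "body_temperature", "eta")
    }
    time = np.empty(s)
    for t in range(s):
        time[t] = litter.time
        rec["x"][t] = litter.positions[:, 0]
        rec["y"][t] = litter.positions[:, 1]
        rec["heading"][t] = litter.headings
        rec["body_temperature"][t] = litter.body_temperatures
        litter, fld = step(litter, config, rng)
        rec["eta"][t] = fld.eta
        if not (
            np.isfinite(litter.body_temperatures).all()
            and np.isfinite(litter.positions).all()
        ):
            raise RuntimeError(
                f"non-finite state at step {t}: check dt and parameter magnitudes"
            )
    traj = Trajectory(
        time=time,
        **rec,
        pup_radius=config.pup_radius,
        seed=used_seed,
        config=config.to_dict(),
    )
    return SimulationResult(
        trajectory=traj,
        final_state=litter,
        summary=metrics_mod.summarize(traj),
        config=config,
        seed=used_seed,
    )


def run_sweep(
    config: SimConfig,
    param: str,
    values,
    replicates: int = 10,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Run ``replicates`` seeded simulations at each parameter value.

    ``param`` is one of ``SWEEPABLE_PARAMS`` (ambient temperature,
    thermogenesis, contact scaling, sensor-noise variance).  Returns one
    row per (value, replicate) with the run seed and summary metrics;
    replicate seeds are drawn once from a master generator so the table
    reproduces exactly from ``base_seed``.
    """
    if param not in SWEEPABLE_PARAMS:
        raise ValueError(f"sweep parameter must be one of {SWEEPABLE_PARAMS}, got {param!r}")
    values = list(values)
    master = np.random.default_rng(config.seed if base_seed is None else base_seed)
    seeds = master.integers(0, 2**31 - 1, size=(len(values), replicates))
    rows = []
    for vi, value in enumerate(values):
        thermal = config.thermal.__class__(
            **{**config.thermal.__dict__, param: float(value)}
        )
        cfg = config.replace(thermal=thermal)
        for rep in range(replicates):
            result = run_simulation(cfg, seed=int(seeds[vi, rep]))
            s = result.summary
            rows.append(
                {
                    "param": param,
                    "value": float(value),
                    "replicate": rep,
                    "seed": int(seeds[vi, rep]),
                    "huddling": s.huddling,
                    "mean_body_temperature": s.mean_body_temperature,
                    "pup_flow": s.pup_flow,
                    "mean_subgroups": s.mean_subgroups,
                    "mean_largest_aggregate": s.mean_largest_aggregate,
                    "max_aggregate_size": s.max_aggregate_size,
                }
            )
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a sweep table to one row per parameter value.

    Reports the mean and the standard error over replicate runs for each
    summary metric (SE = sd/sqrt(replicates)).
    """
    metrics_cols = [
        "huddling", "mean_body_temperature", "pup_flow",
        "mean_subgroups", "mean_largest_aggregate",
    ]
    grouped = table.groupby("value")
    out = grouped[metrics_cols].mean().add_suffix("_mean")
    n = grouped.size()
    for col in metrics_cols:
        out[col + "_se"] = grouped[col].std(ddof=1) / np.sqrt(n)
    out["replicates"] = n
    return out.reset_index()
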