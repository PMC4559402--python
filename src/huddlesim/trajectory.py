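"""Time-indexed record of a simulation run."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Per-step, per-pup record of a run (settle phase excluded).

    Record s is the state from which step s was taken (so record 0 is the
    settled initial state) together with the exposed fraction eta sensed
    at that step.  Arrays are shaped (steps, n_pups).
    """

    time: np.ndarray  # (S,)
    x: np.ndarray  # (S, N)
    y: np.ndarray
    heading: np.ndarray
    body_temperature: np.ndarray
    eta: np.ndarray
    pup_radius: float = 1.0
    seed: int | None = None
    config: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.time)

    @property
    def n_pups(self) -> int:
        return 0 if self.n_steps == 0 else self.x.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per (step, pup)."""
        s, n = self.x.shape
        return pd.DataFrame(
            {
                "t": np.repeat(self.time, n),
                "pup": np.tile(np.arange(n), s),
                "x": self.x.ravel(),
                "y": self.y.ravel(),
                "theta": self.heading.ravel(),
                "t_b": self.body_temperature.ravel(),
                "eta": self.eta.ravel(),
            }
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        pup_radius: float = 1.0,
        seed: int | None = None,
        config: dict | None = None,
    ) -> "Trajectory":
        n = int(frame["pup"].max()) + 1 if len(frame) else 0
        if len(frame) % max(n, 1):
            raise ValueError("trajectory table is truncated: rows not a multiple of pup count")
        s = len(frame) // max(n, 1)

        def grid(col: str) -> np.ndarray:
            return frame[col].to_numpy(dtype=float).reshape(s, n)

        return cls(
            time=frame["t"].to_numpy(dtype=float).reshape(s, n)[:, 0] if s else np.empty(0),
            x=grid("x"),
            y=grid("y"),
            heading=grid("theta"),
            body_temperature=grid("t_b"),
            eta=grid("eta"),
            pup_radius=pup_radius,
            seed=seed,
            config=dict(config or {}),
        )
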