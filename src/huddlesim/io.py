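"""Trajectory and manifest serialisation.

Trajectories are stored as a plain CSV (one row per step and pup, columns
t, pup, x, y, theta, t_b, eta, preceded by ``# key=value`` header
comments) with a JSON metadata sidecar ``<name>.meta.json`` holding the
config echo, seed, pup radius and format version.  Text formats keep runs
small and diff-able.
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
import warnings
from pathlib import Path

import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "FORMAT_VERSION",
    "TrajectoryFormatError",
    "write_trajectory",
    "read_trajectory",
    "write_manifest",
]

FORMAT_VERSION = 1
_REQUIRED_COLUMNS = ["t", "pup", "x", "y", "theta", "t_b", "eta"]


class TrajectoryFormatError(ValueError):
    """Raised for malformed trajectory files."""


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_trajectory(traj: Trajectory, path: str | Path, float_format: str = "%.10g") -> Path:
    """Write CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# format_version={FORMAT_VERSION}\n")
        fh.write(f"# seed={traj.seed}\n")
        fh.write(f"# pup_radius={traj.pup_radius}\n")
        traj.to_frame().to_csv(fh, index=False, float_format=float_format)
    meta = {
        "format_version": FORMAT_VERSION,
        "seed": traj.seed,
        "pup_radius": traj.pup_radius,
        "n_steps": traj.n_steps,
        "n_pups": traj.n_pups,
        "config": traj.config,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    """Round-trip reader for :func:`write_trajectory` output.

    Header/sidecar disagreements on the seed emit a warning and the
    sidecar wins; a missing sidecar falls back to the header comments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            header[key.strip()] = value.strip()
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    version = meta.get("format_version", header.get("format_version"))
    if version is not None and int(version) != FORMAT_VERSION:
        raise TrajectoryFormatError(
            f"unsupported trajectory format version {version} (expected {FORMAT_VERSION})"
        )

    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TrajectoryFormatError(f"trajectory file missing column(s): {missing}")
    if frame[_REQUIRED_COLUMNS].isna().any().any():
        raise TrajectoryFormatError("trajectory file contains truncated/empty rows")

    header_seed = header.get("seed")
    header_seed = None if header_seed in (None, "None") else int(header_seed)
    seed = meta.get("seed", header_seed)
    if sidecar.exists() and "seed" in meta and header_seed is not None and meta["seed"] != header_seed:
        warnings.warn(
            f"seed mismatch between sidecar ({meta['seed']}) and CSV header "
            f"({header_seed}); using the sidecar value",
            stacklevel=2,
        )
    pup_radius = float(meta.get("pup_radius", header.get("pup_radius", 1.0)))
    try:
        return Trajectory.from_frame(
            frame, pup_radius=pup_radius, seed=seed, config=meta.get("config", {})
        )
    except ValueError as exc:
        raise TrajectoryFormatError(str(exc)) from exc


def write_manifest(
    out_dir: str | Path,
    config,
    seeds,
    outputs,
    started: float | None = None,
) -> Path:
    """Reproducibility manifest: config echo, seeds, outputs, timing."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict() if dataclasses.is_dataclass(config) else dict(config)
    manifest = {
        "software": {"name": "huddlesim", "version": __version__},
        "config": cfg,
        "seeds": [int(s) for s in seeds],
        "outputs": [str(Path(p).name) for p in outputs],
        "timing": {
            "started_unix": started,
            "elapsed_s": None if started is None else round(_time.time() - started, 3),
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
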