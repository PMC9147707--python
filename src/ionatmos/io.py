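"""Trajectory ingestion and run configuration.

Trajectories come in as a PDB topology plus DCD or XTC coordinates through
MDAnalysis; the loader resolves named selections into particle groups and
returns the package's in-memory ensemble.  Configurations are TOML (read
with the standard-library parser) or JSON files mirroring the same schema;
the canonical serialized form is JSON, which makes configs diffable and
hashable for provenance.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import TrajectoryEnsemble


def load_trajectory(
    topology,
    coordinates,
    selections: dict | None = None,
    box=None,
    dt: float | None = None,
    start: int = 0,
    stop: int | None = None,
    step: int = 1,
) -> TrajectoryEnsemble:
    """Read a PDB/DCD or PDB/XTC trajectory into a TrajectoryEnsemble.

    ``selections`` maps group names to MDAnalysis selection strings (e.g.
    ``{"na": "name NA"}``).  The box must be present in the trajectory or
    given explicitly; ``dt`` falls back to the trajectory metadata.
    Frames are streamed from disk one at a time and only the requested
    range is materialized.
    """
    import MDAnalysis as mda

    topology, coordinates = str(topology), str(coordinates)
    for p in (topology, coordinates):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    u = mda.Universe(topology, coordinates)
    groups = {}
    for name, sel in (selections or {}).items():
        ag = u.select_atoms(sel)
        if len(ag) == 0:
            raise ValueError(f"selection {sel!r} for group {name!r} matched 0 atoms")
        groups[name] = ag.ix.copy()
    frames = []
    n_read = 0
    try:
        for ts in u.trajectory[start:stop:step]:
            frames.append(u.atoms.positions.astype(float).copy())
            n_read += 1
    except (OSError, EOFError, ValueError) as exc:
        raise IOError(
            f"trajectory truncated after frame {start + n_read * step - step}: {exc}"
        ) from exc
    if not frames:
        raise ValueError("no frames read")
    if coordinates.endswith(".dcd") and stop is None and step == 1:
        # compare against the frame count declared in the DCD header; the
        # reader silently stops at the last complete frame of a cut file
        with open(coordinates, "rb") as fh:
            head = fh.read(12)
        declared = int.from_bytes(head[8:12], "little", signed=True)
        if declared > 0 and start + len(frames) < declared:
            raise IOError(
                f"trajectory truncated: header declares {declared} frames, "
                f"last good frame is {start + len(frames) - 1}"
            )
    if box is None:
        dims = u.trajectory.ts.dimensions
        if dims is None or not np.all(np.asarray(dims[:3]) > 0):
            raise ValueError("no box in trajectory; pass box= explicitly")
        box = np.asarray(dims[:3], dtype=float)
    if dt is None:
        dt = float(getattr(u.trajectory, "dt", 1.0)) * step
    return TrajectoryEnsemble(np.stack(frames), np.asarray(box, float), dt, groups)


def iter_frames(topology, coordinates, chunk: int = 1000):
    """Stream frames in chunks of positions without materializing all."""
    import MDAnalysis as mda

    u = mda.Universe(str(topology), str(coordinates))
    buf = []
    for ts in u.trajectory:
        buf.append(u.atoms.positions.astype(float).copy())
        if len(buf) == chunk:
            yield np.stack(buf)
            buf = []
    if buf:
        yield np.stack(buf)


# ---------------------------------------------------------------------------
# run configuration

_DEFAULTS = {
    "scene": {
        "box": [44.8, 40.0, 27.2],
        "d": 22.4,
        "radius": 10.0,
        "n_na": 42,
        "n_cl": 10,
        "frame_interval": 0.1,
        "n_frames": 20000,
        "jitter_amplitude": 1.0,
        "jitter_tau": 5.0,
        "d_slow": 0.06,
        "d_fast": 0.21,
    },
    "grid": {"spacing": 1.0},
    "zones": {"shell": [10.0, 14.0]},
    "density": {"enabled": True, "xi": 3.0, "shell_width": 0.5},
    "entropy": {"enabled": True, "n_ring_points": 24, "ring_radius": 11.0},
    "diffusion": {
        "enabled": True,
        "t1": 1.0,
        "t2": 2.0,
        "capture_radius": 1.0,
        "min_events": 10,
        "n_blocks": 9,
        "overlap_frac": 0.7,
        "min_sep": 2.8,
        "gap_tolerance": 2,
    },
    "energetics": {"enabled": True, "frame_stride": 100},
    "pmf": {
        "enabled": True,
        "k": 2.0,
        "x0": 26.0,
        "noise_sd": 1.0,
        "samples_per_bin": 400,
    },
    "stats": {"enabled": True},
    "run": {"seed": 1, "log_level": "info"},
}


def _merge(base: dict, update: dict) -> dict:
    out = {k: (v.copy() if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in update.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults merged in)."""

    data: dict

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "input" in d and "scene" in d:
            raise ValueError(
                "give either input files or a synthetic scene spec, not both"
            )
        cfg = cls(_merge(_DEFAULTS, d))
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            raw = json.loads(path.read_text())
        return cls.from_dict(raw)

    def validate(self) -> None:
        d = self.data
        sc = d["scene"]
        if len(sc["box"]) != 3 or any(b <= 0 for b in sc["box"]):
            raise ValueError("scene.box must be three positive lengths")
        if not 0 < sc["d"] < sc["box"][0]:
            raise ValueError("scene.d must be positive and fit in the box")
        if d["grid"]["spacing"] <= 0:
            raise ValueError("grid.spacing must be positive")
        df = d["diffusion"]
        if not 0 < df["overlap_frac"] <= 1:
            raise ValueError("diffusion.overlap_frac must be in (0, 1]")
        if sc["frame_interval"] > df["t1"] and df["enabled"]:
            raise ValueError("frame interval coarser than diffusion t1")

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()

    def __getitem__(self, key):
        return self.data[key]
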