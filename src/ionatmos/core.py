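"""Shared in-memory containers for trajectory analysis.

Units throughout the package: Å for lengths, ps for times, kcal/mol for
energies, elementary charge e for charges, k_B for entropies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrajectoryEnsemble:
    """Frames of particle positions with a periodic orthorhombic box.

    Parameters
    ----------
    positions : ndarray, shape (n_frames, n_atoms, 3)
        Wrapped coordinates in Å.
    box : ndarray, shape (3,)
        Orthorhombic box edge lengths in Å.
    dt : float
        Time between stored frames in ps.
    groups : dict[str, ndarray]
        Named particle groups (e.g. ``"na"``, ``"dna1"``) as integer index
        arrays into the atom axis.
    """

    positions: np.ndarray
    box: np.ndarray
    dt: float
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.groups = {k: np.asarray(v, dtype=int) for k, v in self.groups.items()}

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def group(self, name: str) -> np.ndarray:
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(
                f"unknown particle group {name!r}; available: {sorted(self.groups)}"
            ) from None

    def group_positions(self, name: str) -> np.ndarray:
        """Positions of one named group, shape (n_frames, n_group, 3)."""
        return self.positions[:, self.group(name), :]

    def wrapped(self) -> np.ndarray:
        """Positions wrapped into [0, box) on every axis."""
        return np.mod(self.positions, self.box)

    def unwrapped(self, group: str | None = None) -> np.ndarray:
        """Continuous (image-consistent) coordinates.

        Rebuilt by accumulating minimum-image displacements between
        consecutive frames; valid as long as no particle moves more than
        half a box edge per frame.
        """
        pos = self.positions if group is None else self.group_positions(group)
        disp = np.diff(pos, axis=0)
        disp -= self.box * np.round(disp / self.box)
        out = np.empty_like(pos)
        out[0] = pos[0]
        np.cumsum(disp, axis=0, out=out[1:])
        out[1:] += pos[0]
        return out


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image convention applied to displacement vectors."""
    return delta - box * np.round(delta / box)
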