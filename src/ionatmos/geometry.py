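"""Spatial bookkeeping for a pair of parallel duplexes.

Two duplexes are modelled as cylinders of radius ``R_DNA`` (10 Å) with axes
along z, located by their helical centers c1 and c2.  Space around them is
partitioned into five zones:

- ``inside1`` / ``inside2`` — in-plane distance to the corresponding center
  smaller than ``R_DNA``;
- ``interface`` — the slab between the two cylinders, with DNA1/DNA2
  ownership split at the midpoint of the two centers' x coordinates
  (a point exactly at the midpoint belongs to DNA1);
- ``noninterface1`` / ``noninterface2`` — each duplex's outward hemispace
  extending into bulk solution.

Groove labels (minor/major) live on a radial shell just outside each
cylinder surface and are assigned by an angular-sector rule relative to the
two backbone strands' phase angles; the delimitation is a parametric
construction of this package (see docs/methods.md).
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import TrajectoryEnsemble

R_DNA_DEFAULT = 10.0

ZONE_CODES = {
    "inside1": 0,
    "inside2": 1,
    "interface": 2,
    "noninterface1": 3,
    "noninterface2": 4,
}
ZONE_NAMES = {v: k for k, v in ZONE_CODES.items()}

GROOVE_CODES = {"none": 0, "minor": 1, "major": 2}
GROOVE_NAMES = {v: k for k, v in GROOVE_CODES.items()}


@dataclass(frozen=True)
class GridSpec:
    """A regular 3-D grid of voxel centers inside a periodic box.

    Grid points are voxel centers; a voxel owns the half-open cube
    ``[center - s/2, center + s/2)`` on each axis.
    """

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]
    box_lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(n < 1 for n in self.shape):
            raise ValueError("shape components must be >= 1")
        if any(b <= 0 for b in self.box_lengths):
            raise ValueError("box lengths must be positive")
        for o, n, b in zip(self.origin, self.shape, self.box_lengths):
            if (n - 1) * self.spacing > b + 1e-9:
                raise ValueError("grid does not fit inside the box")

    @classmethod
    def from_box(cls, box_lengths, spacing: float = 1.0) -> "GridSpec":
        box = tuple(float(b) for b in box_lengths)
        shape = tuple(int(np.floor(b / spacing)) for b in box)
        origin = tuple(spacing / 2.0 for _ in box)
        return cls(origin, spacing, shape, box)

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        return float(self.spacing**3)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing * np.arange(self.shape[i]) for i in range(3)
        )

    def points(self) -> np.ndarray:
        """All voxel centers, shape (n_points, 3), x fastest-varying last."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def spans_box(self, rtol: float = 1e-6) -> bool:
        return all(
            abs(n * self.spacing - b) <= rtol * b
            for n, b in zip(self.shape, self.box_lengths)
        )

    def voxel_index(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map positions to flat voxel indices under half-open ownership.

        Returns (flat_indices, in_grid_mask); positions outside the grid get
        mask False.  If the grid tiles the whole box the indexing is
        periodic and every position lands in a voxel.
        """
        pos = np.mod(np.asarray(positions, dtype=float), self.box_lengths)
        idx = np.floor(
            (pos - np.asarray(self.origin) + self.spacing / 2.0) / self.spacing
        ).astype(int)
        shape = np.asarray(self.shape)
        if self.spans_box():
            idx = np.mod(idx, shape)
            mask = np.ones(len(idx), dtype=bool)
        else:
            mask = np.all((idx >= 0) & (idx < shape), axis=1)
        flat = np.ravel_multi_index(
            tuple(np.clip(idx, 0, shape - 1).T), self.shape, mode="clip"
        )
        return flat, mask


@dataclass
class HelicalFrame:
    """Per-frame helical center lines of the two duplexes.

    ``c1`` and ``c2`` hold the in-plane (x, y) centers per frame and z-slab,
    shape (n_frames, n_slabs, 2).  ``d`` is the time-averaged in-plane
    center separation.
    """

    c1: np.ndarray
    c2: np.ndarray
    d: float
    R_DNA: float = R_DNA_DEFAULT

    def __post_init__(self) -> None:
        self.c1 = np.atleast_3d(np.asarray(self.c1, dtype=float))
        self.c2 = np.atleast_3d(np.asarray(self.c2, dtype=float))
        if self.d <= 0:
            raise ValueError("interhelical distance d must be positive")

    @classmethod
    def from_static_centers(cls, c1_xy, c2_xy, R_DNA: float = R_DNA_DEFAULT):
        c1 = np.asarray(c1_xy, dtype=float).reshape(1, 1, 2)
        c2 = np.asarray(c2_xy, dtype=float).reshape(1, 1, 2)
        d = float(np.linalg.norm(c1[0, 0] - c2[0, 0]))
        return cls(c1, c2, d, R_DNA)

    def mean_center(self, which: int) -> np.ndarray:
        c = self.c1 if which == 1 else self.c2
        return np.nanmean(c, axis=(0, 1))

    def per_frame_d(self) -> np.ndarray:
        """In-plane separation of the slab-averaged centers, per frame."""
        c1 = np.nanmean(self.c1, axis=1)
        c2 = np.nanmean(self.c2, axis=1)
        return np.linalg.norm(c1 - c2, axis=1)


@dataclass
class ZoneMask:
    """Per-grid-point categorical zone and groove labels."""

    grid: GridSpec
    labels: np.ndarray  # int8 codes per ZONE_CODES, shape (n_points,)
    groove_labels: np.ndarray = field(default=None)  # int8 per GROOVE_CODES
    owner: np.ndarray = field(default=None)  # 1 or 2: duplex ownership

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (self.grid.n_points,):
            raise ValueError("labels must have one entry per grid point")
        if self.groove_labels is None:
            self.groove_labels = np.zeros(self.grid.n_points, dtype=np.int8)
        if self.owner is None:
            self.owner = np.zeros(self.grid.n_points, dtype=np.int8)

    def zone_points(self, zone: str, owner: int | None = None) -> np.ndarray:
        mask = self.labels == ZONE_CODES[zone]
        if owner is not None:
            mask &= self.owner == owner
        return mask

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.labels == code)) for name, code in ZONE_CODES.items()
        }

    def save(self, path) -> None:
        """Portable gzipped voxel map: JSON header line + label bytes."""
        header = {
            "grid": {
                "origin": list(self.grid.origin),
                "spacing": self.grid.spacing,
                "shape": list(self.grid.shape),
                "box_lengths": list(self.grid.box_lengths),
            },
            "zone_codes": ZONE_CODES,
            "groove_codes": GROOVE_CODES,
        }
        with open(path, "wb") as raw:
            # mtime pinned to 0 so identical masks produce identical bytes
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
                fh.write((json.dumps(header) + "\n").encode())
                fh.write(self.labels.tobytes())
                fh.write(self.groove_labels.tobytes())
                fh.write(self.owner.tobytes())

    @classmethod
    def load(cls, path) -> "ZoneMask":
        with gzip.open(path, "rb") as fh:
            header = json.loads(fh.readline().decode())
            g = header["grid"]
            grid = GridSpec(
                tuple(g["origin"]), g["spacing"], tuple(g["shape"]),
                tuple(g["box_lengths"]),
            )
            n = grid.n_points
            raw = fh.read()
        labels = np.frombuffer(raw[:n], dtype=np.int8).copy()
        groove = np.frombuffer(raw[n : 2 * n], dtype=np.int8).copy()
        owner = np.frombuffer(raw[2 * n : 3 * n], dtype=np.int8).copy()
        return cls(grid, labels, groove, owner)


def compute_helical_centers(
    traj: TrajectoryEnsemble,
    selection1: str | np.ndarray,
    selection2: str | np.ndarray,
    n_slabs: int = 1,
    R_DNA: float = R_DNA_DEFAULT,
) -> HelicalFrame:
    """Per-frame, per-z-slab in-plane centroids of the two duplex selections.

    ``d`` is the time average of the in-plane distance between the
    slab-averaged centers.
    """

    def resolve(sel):
        idx = traj.group(sel) if isinstance(sel, str) else np.asarray(sel, dtype=int)
        if idx.size == 0:
            raise ValueError("empty selection for helical center computation")
        return idx

    i1, i2 = resolve(selection1), resolve(selection2)
    lz = traj.box[2]
    edges = np.linspace(0.0, lz, n_slabs + 1)

    def centers(idx):
        pos = np.mod(traj.positions[:, idx, :], traj.box)
        out = np.full((traj.n_frames, n_slabs, 2), np.nan)
        slab = np.clip(
            np.digitize(pos[..., 2], edges) - 1, 0, n_slabs - 1
        )  # (T, n_atoms)
        for s in range(n_slabs):
            m = slab == s
            cnt = m.sum(axis=1)
            if np.any(cnt == 0):
                warnings.warn(f"slab {s}: empty in {int((cnt == 0).sum())} frames")
            with np.errstate(invalid="ignore"):
                for ax in range(2):
                    out[:, s, ax] = np.where(
                        cnt > 0,
                        np.sum(pos[..., ax] * m, axis=1) / np.maximum(cnt, 1),
                        np.nan,
                    )
        return out

    c1, c2 = centers(i1), centers(i2)
    hf = HelicalFrame(c1, c2, d=1.0, R_DNA=R_DNA)
    hf.d = float(np.nanmean(hf.per_frame_d()))
    return hf


def assign_zones(grid: GridSpec, hframe: HelicalFrame) -> ZoneMask:
    """Partition grid points into inside/interface/non-interface zones.

    Uses time-averaged centers.  The interface band consists of exterior
    points whose x lies strictly between the two centers' x and whose y is
    within ±R_DNA of the inter-center axis; ownership is split at the
    midpoint x (ties to DNA1).  All remaining exterior points fall to the
    non-interface zone of the duplex on their side of the midpoint.
    """
    c1 = hframe.mean_center(1)
    c2 = hframe.mean_center(2)
    if hframe.d <= 0:
        raise ValueError("degenerate helical frame: d <= 0")
    R = hframe.R_DNA
    pts = grid.points()
    xy = pts[:, :2]
    r1 = np.linalg.norm(xy - c1, axis=1)
    r2 = np.linalg.norm(xy - c2, axis=1)

    labels = np.empty(grid.n_points, dtype=np.int8)
    owner = np.zeros(grid.n_points, dtype=np.int8)

    inside1 = r1 < R
    inside2 = (r2 < R) & ~inside1
    exterior = ~(inside1 | inside2)

    xlo, xhi = sorted((c1[0], c2[0]))
    mid = 0.5 * (c1[0] + c2[0])
    ymid = 0.5 * (c1[1] + c2[1])
    band = (
        exterior
        & (pts[:, 0] > xlo)
        & (pts[:, 0] < xhi)
        & (np.abs(pts[:, 1] - ymid) <= R)
    )
    # side of the midpoint facing DNA1 (tie at the midpoint -> DNA1)
    sgn1 = np.sign(c1[0] - mid)
    to1 = np.sign(pts[:, 0] - mid) * sgn1 >= 0

    labels[inside1] = ZONE_CODES["inside1"]
    labels[inside2] = ZONE_CODES["inside2"]
    owner[inside1] = 1
    owner[inside2] = 2
    labels[band] = ZONE_CODES["interface"]
    owner[band & to1] = 1
    owner[band & ~to1] = 2
    rest = exterior & ~band
    labels[rest & to1] = ZONE_CODES["noninterface1"]
    labels[rest & ~to1] = ZONE_CODES["noninterface2"]
    owner[rest & to1] = 1
    owner[rest & ~to1] = 2
    return ZoneMask(grid, labels, owner=owner)


@dataclass(frozen=True)
class HelixSpec:
    """Idealized double-helix phase geometry for groove delimitation.

    ``phase1``/``phase2`` are the azimuthal phase angles (degrees, at z = 0)
    of the two backbone strands' phosphates; the narrower inter-strand
    sector is the minor groove.  ``rotation2`` rotates duplex 2's pattern.
    """

    rise: float = 3.4  # Å per base step
    twist: float = 36.0  # degrees per base step
    phase1: float = 0.0
    phase2: float = 120.0  # minor-groove sector width = phase2 - phase1
    rotation2: float = 0.0
    phosphate_radius: float = 9.0

    def strand_angles(self, z, duplex: int = 1):
        """Phase angles (radians) of the two strands at height z."""
        base = np.deg2rad(self.twist) * np.asarray(z, dtype=float) / self.rise
        off = np.deg2rad(self.rotation2) if duplex == 2 else 0.0
        t1 = np.deg2rad(self.phase1) + base + off
        t2 = np.deg2rad(self.phase2) + base + off
        return t1, t2

    def phosphate_positions(self, center_xy, lz: float, duplex: int = 1):
        """Discrete phosphate atom positions of both strands along the axis."""
        z = np.arange(0.0, lz, self.rise)
        t1, t2 = self.strand_angles(z, duplex)
        out = []
        for t in (t1, t2):
            out.append(
                np.stack(
                    [
                        center_xy[0] + self.phosphate_radius * np.cos(t),
                        center_xy[1] + self.phosphate_radius * np.sin(t),
                        z,
                    ],
                    axis=1,
                )
            )
        return out[0], out[1]


def _in_sector(phi, lo, width):
    """Is angle phi inside [lo, lo+width) mod 2 pi."""
    return np.mod(phi - lo, 2 * np.pi) < width


def groove_mask(
    hframe: HelicalFrame,
    helix_spec: HelixSpec | None,
    grid: GridSpec,
    shell: tuple[float, float] = (10.0, 14.0),
) -> np.ndarray:
    """Minor/major groove labels on the radial shell around each duplex.

    Shell points (radial distance from the nearer axis within ``shell``) are
    labeled by azimuth: inside the narrower inter-strand sector at their
    height -> minor; the wider sector -> major.  Returns int8 codes per
    :data:`GROOVE_CODES`.
    """
    n = grid.n_points
    if helix_spec is None:
        warnings.warn("no helix_spec provided; groove labels all 'none'")
        return np.zeros(n, dtype=np.int8)
    pts = grid.points()
    out = np.zeros(n, dtype=np.int8)
    c = [hframe.mean_center(1), hframe.mean_center(2)]
    r = [np.linalg.norm(pts[:, :2] - ci, axis=1) for ci in c]
    nearer = np.argmin(np.stack(r, axis=1), axis=1)  # 0 or 1
    width_minor = np.deg2rad(
        np.mod(helix_spec.phase2 - helix_spec.phase1, 360.0)
    )
    for k in (0, 1):
        sel = (nearer == k) & (r[k] >= shell[0]) & (r[k] < shell[1])
        if not np.any(sel):
            continue
        phi = np.arctan2(pts[sel, 1] - c[k][1], pts[sel, 0] - c[k][0])
        t1, _ = helix_spec.strand_angles(pts[sel, 2], duplex=k + 1)
        minor = _in_sector(phi, t1, width_minor)
        out[np.flatnonzero(sel)[minor]] = GROOVE_CODES["minor"]
        out[np.flatnonzero(sel)[~minor]] = GROOVE_CODES["major"]
    return out


def rmsd_rmsf(
    traj: TrajectoryEnsemble,
    selection: str | np.ndarray,
    reference: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame RMSD from a reference and per-atom RMSF about the mean.

    No superposition fit is applied: for systems restrained in place the raw
    deviations are the meaningful quantity.
    """
    idx = (
        traj.group(selection)
        if isinstance(selection, str)
        else np.asarray(selection, dtype=int)
    )
    pos = traj.positions[:, idx, :]
    ref = np.asarray(reference, dtype=float)
    if ref.shape != pos.shape[1:]:
        raise ValueError(
            f"reference atom count {ref.shape} does not match selection "
            f"{pos.shape[1:]}"
        )
    dev = pos - ref
    rmsd = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=1))
    mean_pos = pos.mean(axis=0)
    fluct = pos - mean_pos
    rmsf = np.sqrt(np.mean(np.sum(fluct**2, axis=2), axis=0))
    return rmsd, rmsf
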