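"""Grid-localized diffusion coefficients, block-consistency filtering,
site merging and residence times for ions around the duplexes.

The local diffusion coefficient at a grid point uvw is estimated by the
finite-difference expression

    6 D_uvw = < (r(t2) - r(t0))^2 - (r(t1) - r(t0))^2 > / (t2 - t1)

accumulated over every capture event (an ion within the capture radius,
1.0 Å, of the grid point at time origin t0), with t1 = 1 ps and t2 = 2 ps.
The absolute value is applied to the averaged difference, not per event
(per-event absolute values bias D upward at low counts); a switch selects
the per-event reading.  On force-free Brownian motion the signed-mean
estimator is exactly unbiased for any t1 < t2.

Noise control follows a nine-block protocol: the trajectory is split into
equal-frame blocks, a point is retained when it has events in at least
ceil(overlap_frac * n_blocks) blocks, and retained points are smoothed by
weighted averaging of up to six nearest neighbors until all sites are more
than 2.8 Å apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import TrajectoryEnsemble, minimum_image
from .geometry import GridSpec


@dataclass
class DiffusionMap:
    """Per-grid-point diffusion coefficients with capture-event counts."""

    grid: GridSpec
    D: np.ndarray  # Å²/ps, NaN where n_events == 0
    n_events: np.ndarray
    t1: float = 1.0
    t2: float = 2.0
    capture_radius: float = 1.0
    min_events: int = 10

    @property
    def reported(self) -> np.ndarray:
        """Mask of points with enough events to report a coefficient."""
        return self.n_events >= self.min_events

    def to_frame(self) -> pd.DataFrame:
        pts = self.grid.points()
        return pd.DataFrame(
            {
                "x": pts[:, 0],
                "y": pts[:, 1],
                "z": pts[:, 2],
                "D": self.D,
                "n_events": self.n_events,
            }
        )


def local_diffusion_map(
    traj: TrajectoryEnsemble,
    species: str,
    grid: GridSpec,
    t1: float = 1.0,
    t2: float = 2.0,
    capture_radius: float = 1.0,
    min_events: int = 10,
    abs_mode: str = "of_mean",
    frame_range: tuple[int, int] | None = None,
    chunk_frames: int = 512,
) -> DiffusionMap:
    """Finite-difference local diffusion map on a regular grid.

    Capture events are counted at every valid time origin (overlapping
    origins allowed); displacements use periodically unwrapped coordinates,
    capture uses wrapped ones.  ``abs_mode`` is ``"of_mean"`` (default) or
    ``"per_event"``.
    """
    if abs_mode not in ("of_mean", "per_event"):
        raise ValueError("abs_mode must be 'of_mean' or 'per_event'")
    dt = traj.dt
    if dt > t1 + 1e-9:
        raise ValueError(
            f"frame interval {dt} ps is coarser than t1 = {t1} ps; "
            "cannot form the first lag"
        )
    k1 = int(round(t1 / dt))
    k2 = int(round(t2 / dt))
    if abs(k1 * dt - t1) > 1e-6 or abs(k2 * dt - t2) > 1e-6:
        raise ValueError("frame interval must divide t1 and t2")

    unw = traj.unwrapped(species)
    wrp = np.mod(traj.group_positions(species), traj.box)
    lo, hi = frame_range if frame_range is not None else (0, traj.n_frames)
    n_valid = hi - lo - k2
    if n_valid < 1:
        raise ValueError("trajectory too short for the t2 lag")

    sums = np.zeros(grid.n_points)
    counts = np.zeros(grid.n_points, dtype=np.int64)
    origin = np.asarray(grid.origin)
    shape = np.asarray(grid.shape)
    spacing = grid.spacing
    periodic = grid.spans_box()
    reach = int(np.ceil(capture_radius / spacing))
    offsets = np.array(list(product(range(-reach, reach + 1), repeat=3)))
    box = traj.box

    for c0 in range(lo, lo + n_valid, chunk_frames):
        c1 = min(c0 + chunk_frames, lo + n_valid)
        sl = slice(c0, c1)
        d2 = unw[c0 + k2 : c1 + k2] - unw[sl]
        d1 = unw[c0 + k1 : c1 + k1] - unw[sl]
        x = np.sum(d2**2, axis=2) - np.sum(d1**2, axis=2)  # (chunk, N)
        if abs_mode == "per_event":
            x = np.abs(x)
        pos = wrp[sl].reshape(-1, 3)
        xv = x.reshape(-1)
        base = np.round((pos - origin) / spacing).astype(int)
        for off in offsets:
            idx = base + off
            if periodic:
                idx_w = np.mod(idx, shape)
                valid = np.ones(len(idx), dtype=bool)
            else:
                idx_w = idx
                valid = np.all((idx >= 0) & (idx < shape), axis=1)
                idx_w = np.clip(idx, 0, shape - 1)
            centers = origin + idx * spacing  # unwrapped candidate center
            dist2 = np.sum((pos - centers) ** 2, axis=1)
            hit = valid & (dist2 < capture_radius**2)
            if not np.any(hit):
                continue
            flat = np.ravel_multi_index(tuple(idx_w[hit].T), grid.shape)
            np.add.at(sums, flat, xv[hit])
            np.add.at(counts, flat, 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    if abs_mode == "of_mean":
        mean = np.abs(mean)
    D = mean / (6.0 * (t2 - t1))
    D[counts == 0] = np.nan
    return DiffusionMap(grid, D, counts, t1, t2, capture_radius, min_events)


@dataclass
class BlockFilterResult:
    """Across-block consistency filter output."""

    retained: np.ndarray  # bool mask over grid points
    mean_D: np.ndarray  # across-block mean at retained points (NaN elsewhere)
    sd_D: np.ndarray
    total_events: np.ndarray
    n_blocks: int
    overlap_frac: float


def block_consistency_filter(
    maps: list[DiffusionMap], overlap_frac: float = 0.7
) -> BlockFilterResult:
    """Retain grid points occupied in >= ceil(overlap_frac * n) blocks.

    With the nine-block default and overlap 0.7 the threshold is 7 blocks.
    Retained points carry the across-block mean and SD of D over the blocks
    in which they have events.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 blocks")
    n = len(maps)
    n_points = maps[0].grid.n_points
    for m in maps[1:]:
        if m.grid != maps[0].grid:
            raise ValueError("all blocks must share one grid")
    present = np.stack([m.n_events > 0 for m in maps])  # (n, P)
    dvals = np.stack([m.D for m in maps])
    threshold = int(np.ceil(overlap_frac * n))
    retained = present.sum(axis=0) >= threshold
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        masked = np.where(present, dvals, np.nan)
        mean = np.nanmean(masked, axis=0)
        sd = np.nanstd(masked, axis=0, ddof=1)
    mean[~retained] = np.nan
    sd[~retained] = np.nan
    total = np.sum([m.n_events for m in maps], axis=0)
    return BlockFilterResult(
        retained, mean, sd, total, n, overlap_frac
    )


@dataclass
class SiteSet:
    """Merged spatial sites carrying a smoothed observable."""

    positions: np.ndarray  # (M, 3)
    values: np.ndarray
    weights: np.ndarray  # event-count weights
    contributors: list = field(default_factory=list)
    min_separation: float = 2.8
    observable: str = "diffusion"

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "value": self.values,
                "weight": self.weights,
                "n_contributors": [len(c) for c in self.contributors],
            }
        )


def merge_sites(
    positions: np.ndarray,
    values: np.ndarray,
    weights: np.ndarray,
    k_neighbors: int = 6,
    min_sep: float = 2.8,
    observable: str = "diffusion",
) -> SiteSet:
    """Agglomerate points by weighted averaging until all sites separate.

    While any two sites are within ``min_sep`` of each other, the member of
    the closest offending pair with the lowest index absorbs up to
    ``k_neighbors`` of its nearest neighbors within ``min_sep`` (weighted
    average of position and value, weights summed).  Ordering is
    deterministic: closest pair first, ties broken by lowest site index.
    Total weight is conserved and merged sites stay inside the convex hull
    of their contributors.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 3).copy()
    val = np.asarray(values, dtype=float).copy()
    wgt = np.asarray(weights, dtype=float).copy()
    if np.any(wgt <= 0):
        raise ValueError("weights must be positive")
    contrib = [[i] for i in range(len(pos))]
    while len(pos) > 1:
        tree = cKDTree(pos)
        pairs = tree.query_pairs(min_sep, output_type="ndarray")
        if len(pairs) == 0:
            break
        d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
        order = np.lexsort((pairs[:, 1], pairs[:, 0], d))
        i, j = sorted(pairs[order[0]])
        # site i absorbs up to k nearest neighbors within min_sep
        dist, nbr = tree.query(pos[i], k=min(k_neighbors + 1, len(pos)))
        dist, nbr = np.atleast_1d(dist), np.atleast_1d(nbr)
        members = [i] + [
            int(b) for b, dd in zip(nbr, dist) if b != i and dd <= min_sep
        ]
        w = wgt[members]
        new_pos = np.average(pos[members], axis=0, weights=w)
        new_val = float(np.average(val[members], weights=w))
        new_contrib = sorted(set(sum((contrib[m] for m in members), [])))
        keep = np.setdiff1d(np.arange(len(pos)), members[1:])
        pos, val, wgt = pos[keep], val[keep], wgt[keep]
        contrib = [contrib[m] for m in keep]
        new_i = int(np.searchsorted(keep, i))
        pos[new_i] = new_pos
        val[new_i] = new_val
        wgt[new_i] = w.sum()
        contrib[new_i] = new_contrib
    return SiteSet(pos, val, wgt, contrib, min_sep, observable)


def residence_times(
    traj: TrajectoryEnsemble,
    species: str,
    site_positions: np.ndarray,
    radius: float = 1.0,
    gap_tolerance: int = 2,
) -> pd.DataFrame:
    """Per-site residence-time statistics (ps).

    A residence is a maximal visit of one ion within ``radius`` of a site,
    allowing interruptions of at most ``gap_tolerance`` frames; its
    duration counts every frame of the (gap-bridged) span.  Returns a
    frame with per-site mean and maximum residence time and visit count.
    """
    sites = np.asarray(site_positions, dtype=float).reshape(-1, 3)
    if len(sites) == 0:
        raise ValueError("empty site set")
    if traj.dt > 0.1 + 1e-12:
        warnings.warn(
            f"frame interval {traj.dt} ps is coarser than the 0.1 ps context; "
            "residence times will be quantized accordingly"
        )
    pos = np.mod(traj.group_positions(species), traj.box)
    rows = []
    for s, site in enumerate(sites):
        delta = minimum_image(pos - site, traj.box)
        inside = np.sum(delta**2, axis=2) < radius**2  # (T, N)
        durations = []
        for i in range(inside.shape[1]):
            idx = np.flatnonzero(inside[:, i])
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(idx) > gap_tolerance + 1)
            starts = np.r_[idx[0], idx[breaks + 1]]
            ends = np.r_[idx[breaks], idx[-1]]
            durations.extend(((ends - starts) + 1) * traj.dt)
        durations = np.asarray(durations)
        rows.append(
            {
                "site": s,
                "x": site[0],
                "y": site[1],
                "z": site[2],
                "mean_residence_ps": durations.mean() if durations.size else np.nan,
                "max_residence_ps": durations.max() if durations.size else np.nan,
                "n_visits": int(durations.size),
            }
        )
    return pd.DataFrame(rows)
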