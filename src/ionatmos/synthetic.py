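"""Synthetic ion-trajectory and fixture generators with known ground truth.

The scene generator emulates the study system: a periodic ~99 x 99 x 103 Å
box containing two parallel cylinders of radius 10 Å (stand-ins for the
duplexes, axes along z) decorated with helical surface charges, monovalent
counter-/co-ions at 0.15 M-like number densities, position-dependent ion
mobility (slow groove shell, fast bulk), and a rigid vs. flexible switch
(static vs. thermally jittered surface-charge anchors).  Ions move by
overdamped Langevin (Euler–Maruyama) dynamics; every generator is exactly
reproducible under a fixed seed.

Also provides i.i.d. Gaussian field series (covariance fixtures), force
samples from an analytic potential (PMF fixtures) and a rocksalt toy charge
lattice (Ewald fixture).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TrajectoryEnsemble, minimum_image

KB_KCAL = 0.0019872041  # kcal/(mol K)
TEMPERATURE = 310.0  # K
KBT = KB_KCAL * TEMPERATURE  # kcal/mol
COULOMB = 332.0637  # kcal Å / (mol e^2)

ION_CHARGES = {"na": +1.0, "cl": -1.0}


class StepSizeError(RuntimeError):
    """Raised when the integrator cannot honor the displacement cap."""


# ---------------------------------------------------------------------------
# mobility maps


class UniformMobility:
    """Spatially constant diffusion coefficient (Å²/ps)."""

    smooth = False

    def __init__(self, D: float):
        if D < 0:
            raise ValueError("D must be >= 0")
        self.D = float(D)

    @property
    def d_max(self) -> float:
        return self.D

    def __call__(self, positions: np.ndarray) -> np.ndarray:
        return np.full(len(positions), self.D)


class _SmoothedMobility:
    """Base for piecewise-constant maps blended over a smoothing length.

    The blend makes D spatially smooth, so the Itô drift-correction term
    grad D is included by the integrator (estimated by central differences).
    """

    smooth = True
    _h = 0.05  # finite-difference step, Å

    def grad(self, positions: np.ndarray) -> np.ndarray:
        g = np.empty_like(positions, dtype=float)
        for ax in range(3):
            dp = positions.copy()
            dm = positions.copy()
            dp[:, ax] += self._h
            dm[:, ax] -= self._h
            g[:, ax] = (self(dp) - self(dm)) / (2 * self._h)
        return g


class SlabMobility(_SmoothedMobility):
    """Slow slab |x - x0| < half_width inside a fast bulk."""

    def __init__(self, x0, half_width, d_slow=0.06, d_fast=0.21, smoothing=2.0):
        if d_slow <= 0 or d_fast <= 0:
            raise ValueError("diffusion coefficients must be positive")
        self.x0, self.half_width = float(x0), float(half_width)
        self.d_slow, self.d_fast = float(d_slow), float(d_fast)
        self.smoothing = float(smoothing)

    @property
    def d_max(self) -> float:
        return max(self.d_slow, self.d_fast)

    def __call__(self, positions: np.ndarray) -> np.ndarray:
        t = (np.abs(positions[:, 0] - self.x0) - self.half_width) / self.smoothing
        w = 0.5 * (1.0 + np.tanh(2.0 * t))  # 0 deep in slab, 1 in bulk
        return self.d_slow + (self.d_fast - self.d_slow) * w


class GrooveShellMobility(_SmoothedMobility):
    """Slow radial shell around each cylinder axis, fast elsewhere.

    Emulates the observed contrast between slow groove sites (~0.06 Å²/ps)
    and bulk ions (~0.21 Å²/ps).
    """

    def __init__(
        self,
        centers_xy,
        r_lo=9.0,
        r_hi=12.0,
        d_slow=0.06,
        d_fast=0.21,
        smoothing=2.0,
    ):
        if d_slow <= 0 or d_fast <= 0:
            raise ValueError("diffusion coefficients must be positive")
        self.centers_xy = np.asarray(centers_xy, dtype=float).reshape(-1, 2)
        self.r_lo, self.r_hi = float(r_lo), float(r_hi)
        self.d_slow, self.d_fast = float(d_slow), float(d_fast)
        self.smoothing = float(smoothing)

    @property
    def d_max(self) -> float:
        return max(self.d_slow, self.d_fast)

    def __call__(self, positions: np.ndarray) -> np.ndarray:
        r = np.min(
            np.linalg.norm(
                positions[:, None, :2] - self.centers_xy[None, :, :], axis=2
            ),
            axis=1,
        )
        mid = 0.5 * (self.r_lo + self.r_hi)
        half = 0.5 * (self.r_hi - self.r_lo)
        t = (np.abs(r - mid) - half) / self.smoothing
        w = 0.5 * (1.0 + np.tanh(2.0 * t))
        return self.d_slow + (self.d_fast - self.d_slow) * w


# ---------------------------------------------------------------------------
# scene


def helical_surface_charges(
    center_xy,
    lz: float,
    radius: float = 9.0,
    rise: float = 3.4,
    twist: float = 36.0,
    phases=(0.0, 120.0),
    charge: float = -1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Charges on two helical backbone paths around one cylinder axis."""
    z = np.arange(0.0, lz, rise)
    pos, q = [], []
    for phase in phases:
        t = np.deg2rad(phase) + np.deg2rad(twist) * z / rise
        pos.append(
            np.stack(
                [
                    center_xy[0] + radius * np.cos(t),
                    center_xy[1] + radius * np.sin(t),
                    z,
                ],
                axis=1,
            )
        )
        q.append(np.full(len(z), charge))
    return np.concatenate(pos), np.concatenate(q)


@dataclass
class SyntheticScene:
    """Specification of a synthetic two-cylinder ion scene.

    Defaults reproduce the study conditions: a 99 x 99 x 103 Å periodic
    box, cylinders of radius 10 Å at interhelical distance d = 22.4 Å,
    0.15 M-like NaCl plus neutralizing counterions for the helical surface
    charges, frames saved every 0.1 ps.
    """

    box_lengths: tuple[float, float, float] = (99.0, 99.0, 103.0)
    cylinder_centers: tuple[float, float] = (38.3, 60.7)  # x offsets, axes at y=49.5
    cylinder_radius: float = 10.0
    axis_y: float | None = None  # defaults to box_y / 2
    surface_charge_positions: np.ndarray | None = None
    surface_charges: np.ndarray | None = None
    ion_counts: dict = field(default_factory=dict)
    mobility_map: object = None
    flexibility_mode: str = "rigid"  # "rigid" | "flexible"
    jitter_amplitude: float = 1.0  # Å, stationary RMS of anchor jitter
    jitter_tau: float = 5.0  # ps, OU relaxation time
    frame_interval: float = 0.1  # ps
    n_frames: int = 1000
    seed: int = 0
    wall_k: float = 10.0  # kcal/(mol Å²), cylinder soft-repulsion constant
    coulomb_cutoff: float = 12.0  # Å, shifted-truncated Coulomb cutoff
    softcore: float = 1.0  # Å, short-range regularization of 1/r²
    dielectric: float = 78.5  # implicit-water screening of the charge wells
    init_positions: str = "uniform"  # "uniform" | "wells" (counterions seeded
    # one per surface charge; controlled-occupancy recovery fixtures)

    def __post_init__(self) -> None:
        self.box_lengths = tuple(float(b) for b in self.box_lengths)
        if any(b <= 0 for b in self.box_lengths):
            raise ValueError("box lengths must be positive")
        if self.axis_y is None:
            self.axis_y = self.box_lengths[1] / 2.0
        sep = abs(self.cylinder_centers[1] - self.cylinder_centers[0])
        # coincident centers describe a single-cylinder scene
        if 0 < sep <= self.cylinder_radius:
            raise ValueError(
                f"cylinder_radius {self.cylinder_radius} must be smaller than the "
                f"center separation {sep}"
            )
        if self.jitter_amplitude < 0:
            raise ValueError("jitter amplitude must be >= 0")
        if self.flexibility_mode not in ("rigid", "flexible"):
            raise ValueError("flexibility_mode must be 'rigid' or 'flexible'")
        if not self.ion_counts:
            self.ion_counts = {"na": 215, "cl": 91}
        if self.mobility_map is None:
            self.mobility_map = UniformMobility(0.21)
        if self.surface_charge_positions is None:
            pos1, q1 = helical_surface_charges(
                (self.cylinder_centers[0], self.axis_y), self.box_lengths[2]
            )
            pos2, q2 = helical_surface_charges(
                (self.cylinder_centers[1], self.axis_y), self.box_lengths[2]
            )
            self.surface_charge_positions = np.concatenate([pos1, pos2])
            self.surface_charges = np.concatenate([q1, q2])
            self._n_dna1 = len(pos1)
        else:
            self.surface_charge_positions = np.asarray(
                self.surface_charge_positions, dtype=float
            ).reshape(-1, 3)
            if self.surface_charges is None:
                self.surface_charges = np.full(
                    len(self.surface_charge_positions), -1.0
                )
            self.surface_charges = np.asarray(self.surface_charges, dtype=float)
            self._n_dna1 = len(self.surface_charge_positions)
        total = self.total_charge()
        if abs(total - round(total)) > 1e-9:
            raise ValueError(f"total scene charge {total} is not an integer")

    @property
    def n_dna1(self) -> int:
        """Number of surface charges belonging to the first cylinder."""
        return self._n_dna1

    def total_charge(self) -> float:
        q = float(np.sum(self.surface_charges)) if len(self.surface_charges) else 0.0
        for sp, n in self.ion_counts.items():
            q += ION_CHARGES.get(sp, 0.0) * n
        return q

    def to_json(self) -> str:
        d = {
            "box_lengths": list(self.box_lengths),
            "cylinder_centers": list(self.cylinder_centers),
            "cylinder_radius": self.cylinder_radius,
            "axis_y": self.axis_y,
            "n_surface_charges": int(len(self.surface_charges)),
            "total_surface_charge": float(np.sum(self.surface_charges)),
            "ion_counts": {k: int(v) for k, v in self.ion_counts.items()},
            "flexibility_mode": self.flexibility_mode,
            "jitter_amplitude": self.jitter_amplitude,
            "frame_interval": self.frame_interval,
            "n_frames": self.n_frames,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)


def free_scene(
    box=(30.0, 30.0, 30.0),
    D: float = 0.21,
    n_ions: int = 100,
    n_frames: int = 1000,
    frame_interval: float = 0.1,
    seed: int = 0,
) -> SyntheticScene:
    """Force-free scene: no cylinders, no charges, uniform mobility."""
    return SyntheticScene(
        box_lengths=box,
        cylinder_centers=(0.0, 0.0),
        cylinder_radius=0.0,
        surface_charge_positions=np.zeros((0, 3)),
        surface_charges=np.zeros(0),
        ion_counts={"na": n_ions},
        mobility_map=UniformMobility(D),
        frame_interval=frame_interval,
        n_frames=n_frames,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Brownian dynamics

_DISPLACEMENT_CAP = 0.25  # Å per sub-step (keeps capture-radius logic meaningful)


def _forces(ion_pos, ion_q, anchors, anchor_q, scene) -> np.ndarray:
    """Cylinder soft repulsion + shifted-truncated Coulomb wells."""
    F = np.zeros_like(ion_pos)
    box = np.asarray(scene.box_lengths)
    # soft wall pushing ions out of each cylinder interior
    if scene.cylinder_radius > 0:
        for cx in dict.fromkeys(scene.cylinder_centers):
            dxy = ion_pos[:, :2] - np.array([cx, scene.axis_y])
            dxy[:, 0] -= box[0] * np.round(dxy[:, 0] / box[0])
            dxy[:, 1] -= box[1] * np.round(dxy[:, 1] / box[1])
            r = np.linalg.norm(dxy, axis=1)
            inside = r < scene.cylinder_radius
            if np.any(inside):
                rr = np.maximum(r[inside], 1e-6)
                mag = scene.wall_k * (scene.cylinder_radius - rr)
                F[inside, :2] += mag[:, None] * dxy[inside] / rr[:, None]
    if len(anchors):
        delta = minimum_image(ion_pos[:, None, :] - anchors[None, :, :], box)
        r2 = np.sum(delta**2, axis=2) + scene.softcore**2
        r = np.sqrt(r2)
        rc = scene.coulomb_cutoff
        # force-shifted truncation: F(r) = C q q' (1/r^2 - 1/rc^2), 0 beyond rc;
        # C is screened by the implicit-water dielectric
        ceff = COULOMB / scene.dielectric
        mag = ceff * ion_q[:, None] * anchor_q[None, :] * (1.0 / r2 - 1.0 / rc**2)
        mag[r > rc] = 0.0
        F += np.sum((mag / r)[:, :, None] * delta, axis=1)
    return F


def simulate_ion_cloud(scene: SyntheticScene) -> TrajectoryEnsemble:
    """Overdamped-Langevin ion trajectories for a synthetic scene.

    Euler–Maruyama with the per-sub-step displacement capped at 0.25 Å by
    sub-stepping; position-dependent mobility is handled in the Itô
    convention with a grad-D drift correction when the map is smooth.
    Force-free uniform-mobility scenes use exact Gaussian propagation (the
    analytic solution of the same SDE).  Deterministic under ``scene.seed``.

    The returned trajectory contains the (possibly jittered) surface-charge
    anchors as groups ``dna1``/``dna2`` followed by one group per ion
    species, all wrapped into the periodic box.
    """
    if scene.n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(scene.seed)
    box = np.asarray(scene.box_lengths)

    species = sorted(scene.ion_counts)
    n_ions = int(sum(scene.ion_counts.values()))
    ion_q = np.concatenate(
        [np.full(scene.ion_counts[sp], ION_CHARGES.get(sp, 0.0)) for sp in species]
    ) if n_ions else np.zeros(0)

    anchors0 = scene.surface_charge_positions
    n_anchor = len(anchors0)

    # initial ion positions: uniform in box, outside the cylinders
    pos = rng.uniform(0.0, 1.0, size=(n_ions, 3)) * box
    if scene.cylinder_radius > 0 and n_ions:
        for _ in range(200):
            bad = np.zeros(n_ions, dtype=bool)
            for cx in dict.fromkeys(scene.cylinder_centers):
                dxy = minimum_image(
                    pos[:, :2] - np.array([cx, scene.axis_y]), box[:2]
                )
                bad |= np.linalg.norm(dxy, axis=1) < scene.cylinder_radius
            if not np.any(bad):
                break
            pos[bad] = rng.uniform(0.0, 1.0, size=(int(bad.sum()), 3)) * box
    if scene.init_positions == "wells" and n_anchor and n_ions:
        # seed cations over the charge wells, one per anchor, placed just
        # outside the cylinder wall so occupancy starts matched and relaxed
        na_idx = np.flatnonzero(ion_q > 0)
        n_seed = min(len(na_idx), n_anchor)
        seeded = anchors0[:n_seed].copy()
        if scene.cylinder_radius > 0:
            centers = np.array(
                [[cx, scene.axis_y] for cx in dict.fromkeys(scene.cylinder_centers)]
            )
            dxy = seeded[:, None, :2] - centers[None, :, :]
            k = np.argmin(np.linalg.norm(dxy, axis=2), axis=1)
            rad = seeded[:, :2] - centers[k]
            rn = np.linalg.norm(rad, axis=1)
            target = scene.cylinder_radius + 0.5
            seeded[:, :2] = centers[k] + rad / np.maximum(rn, 1e-9)[:, None] * target
        pos[na_idx[:n_seed]] = seeded

    free = (
        n_anchor == 0
        and scene.cylinder_radius == 0
        and isinstance(scene.mobility_map, UniformMobility)
    )

    n_atoms = n_anchor + n_ions
    out = np.empty((scene.n_frames, n_atoms, 3))

    if free:
        D = scene.mobility_map.D
        sigma = math.sqrt(2.0 * D * scene.frame_interval)
        steps = rng.normal(0.0, sigma, size=(scene.n_frames - 1, n_ions, 3))
        path = np.concatenate([pos[None], pos[None] + np.cumsum(steps, axis=0)])
        out[:, n_anchor:, :] = np.mod(path, box)
    else:
        dmax = scene.mobility_map.d_max
        if dmax > 0:
            dt_sub = _DISPLACEMENT_CAP**2 / (6.0 * dmax)
            # a-priori drift probe: the deterministic step must respect the
            # cap too, with a 2x margin over the initial-configuration force
            if n_ions and (n_anchor or scene.cylinder_radius > 0):
                f0 = _forces(pos, ion_q, anchors0, scene.surface_charges, scene)
                drift_rate = 2.0 * dmax * float(
                    np.max(np.linalg.norm(f0, axis=1), initial=0.0)
                ) / KBT
                if drift_rate > 0:
                    dt_sub = min(dt_sub, _DISPLACEMENT_CAP / drift_rate)
            n_sub = max(1, int(math.ceil(scene.frame_interval / dt_sub)))
            if n_sub > 512:
                raise StepSizeError(
                    f"scene needs {n_sub} sub-steps per frame to keep "
                    f"displacements below {_DISPLACEMENT_CAP} Å "
                    f"(frame_interval={scene.frame_interval} ps, "
                    f"d_max={dmax} Å²/ps, dielectric={scene.dielectric}); "
                    "soften the wells or shorten the frame interval"
                )
        else:
            n_sub = 1
        dt = scene.frame_interval / n_sub

        anchors = anchors0.copy()
        jitter = np.zeros_like(anchors0)
        flexible = scene.flexibility_mode == "flexible" and scene.jitter_amplitude > 0
        if flexible:
            decay = math.exp(-dt / scene.jitter_tau)
            kick = scene.jitter_amplitude * math.sqrt(1.0 - decay**2)
            # start from the stationary distribution
            jitter = rng.normal(0.0, scene.jitter_amplitude, size=anchors0.shape)
            anchors = anchors0 + jitter

        out[0, :n_anchor] = np.mod(anchors, box)
        out[0, n_anchor:] = np.mod(pos, box)
        for f in range(1, scene.n_frames):
            for _ in range(n_sub):
                if flexible:
                    jitter = decay * jitter + kick * rng.normal(
                        size=anchors0.shape
                    )
                    anchors = anchors0 + jitter
                if n_ions:
                    D = scene.mobility_map(pos)
                    if np.any(D <= 0):
                        frozen = D <= 0
                        D = np.where(frozen, 0.0, D)
                    drift = np.zeros_like(pos)
                    if n_anchor or scene.cylinder_radius > 0:
                        F = _forces(
                            pos, ion_q, anchors, scene.surface_charges, scene
                        )
                        drift += F * (D / KBT)[:, None]
                    if scene.mobility_map.smooth:
                        drift += scene.mobility_map.grad(pos)
                    step_det = drift * dt
                    # rare deep-core excursions beyond the probe's margin are
                    # clamped to the cap instead of aborting mid-run
                    norms = np.linalg.norm(step_det, axis=1)
                    over = norms > _DISPLACEMENT_CAP
                    if np.any(over):
                        step_det[over] *= (
                            _DISPLACEMENT_CAP / norms[over]
                        )[:, None]
                    noise = rng.normal(size=pos.shape) * np.sqrt(2.0 * D * dt)[
                        :, None
                    ]
                    # keep coordinates wrapped so the mobility map and the
                    # charge wells are evaluated in the primary cell
                    pos = np.mod(pos + step_det + noise, box)
            out[f, :n_anchor] = np.mod(anchors, box)
            out[f, n_anchor:] = np.mod(pos, box)

    if free:
        # anchors absent by construction (n_anchor == 0)
        pass

    groups: dict[str, np.ndarray] = {}
    if n_anchor:
        groups["dna1"] = np.arange(scene.n_dna1)
        groups["dna2"] = np.arange(scene.n_dna1, n_anchor)
    off = n_anchor
    for sp in species:
        n = scene.ion_counts[sp]
        groups[sp] = np.arange(off, off + n)
        off += n
    return TrajectoryEnsemble(out, box, scene.frame_interval, groups)


# ---------------------------------------------------------------------------
# fixture generators


def gaussian_field_series(
    cov_true: np.ndarray, n_frames: int, seed: int, mean: np.ndarray | None = None
) -> pd.DataFrame:
    """I.i.d. multivariate-Gaussian density series with known covariance.

    Rows are frames, columns grid points.  Raises on non-positive-definite
    input; a single-frame request is allowed but flagged (no covariance is
    estimable from it).
    """
    cov = np.asarray(cov_true, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("cov_true must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("cov_true must be symmetric")
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError("cov_true is not positive definite") from None
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_frames == 1:
        warnings.warn("single frame requested: no covariance is estimable")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, cov.shape[0]))
    data = z @ L.T
    if mean is not None:
        data = data + np.asarray(mean, dtype=float)
    return pd.DataFrame(data, columns=[f"p{i}" for i in range(cov.shape[0])])


def force_samples_from_potential(
    potential,
    bin_range: tuple[float, float],
    bin_width: float,
    samples_per_bin: int,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Force samples -dU/dx + Gaussian noise at every bin center.

    ``potential`` is a callable U(x) in kcal/mol; the derivative is taken by
    central differences (exact for polynomials up to cubic).  Returns a
    long-format frame with columns ``d`` and ``force``.
    """
    lo, hi = bin_range
    if not lo < hi:
        raise ValueError("bin_range must be ordered (lo < hi)")
    if samples_per_bin < 1:
        raise ValueError("samples_per_bin must be >= 1")
    centers = np.arange(lo + bin_width / 2.0, hi, bin_width)
    h = 1e-4
    u = np.vectorize(potential)
    force = -(u(centers + h) - u(centers - h)) / (2 * h)
    rng = np.random.default_rng(seed)
    d = np.repeat(centers, samples_per_bin)
    f = np.repeat(force, samples_per_bin)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    else:
        f = f.copy()
    return pd.DataFrame({"d": d, "force": f})


def toy_charge_lattice(
    kind: str = "rocksalt", cells_per_edge: int = 1, lattice_constant: float = 4.0
):
    """Alternating ±1 charges on a cubic lattice in a commensurate box.

    ``lattice_constant`` is the nearest-neighbor (+/-) separation; one
    "cell" is the conventional 2x2x2 rocksalt cube of 8 charges, so
    ``cells_per_edge=1`` gives 8 charges.  Exactly neutral.
    """
    from .energetics import ChargeSystem

    if kind != "rocksalt":
        raise ValueError(f"unknown lattice kind {kind!r}")
    if cells_per_edge < 1:
        raise ValueError("cells_per_edge must be >= 1")
    n = 2 * cells_per_edge
    i, j, k = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    positions = (
        np.stack([i.ravel(), j.ravel(), k.ravel()], axis=1).astype(float)
        * lattice_constant
        + lattice_constant / 2.0
    )
    charges = np.where((i + j + k).ravel() % 2 == 0, 1.0, -1.0)
    box = np.full(3, n * lattice_constant)
    labels = np.where(charges > 0, "na", "cl")
    return ChargeSystem(positions, charges, box, labels)


# ---------------------------------------------------------------------------
# standard-format output


def write_scene(
    traj: TrajectoryEnsemble, scene: SyntheticScene, outdir, prefix: str = "scene"
) -> dict:
    """Write PDB topology + DCD coordinates + JSON scene descriptor.

    Downstream modules consume synthetic and real data through the same
    loader this way.
    """
    import MDAnalysis as mda

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = np.empty(traj.n_atoms, dtype=object)
    names[:] = "X"
    for g, label in (("dna1", "D1"), ("dna2", "D2"), ("na", "NA"), ("cl", "CL")):
        if g in traj.groups:
            names[traj.groups[g]] = label
    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    u.add_TopologyAttr("name", names.tolist())
    u.add_TopologyAttr("resname", ["ION"])
    dims = [*traj.box, 90.0, 90.0, 90.0]
    pdb_path = outdir / f"{prefix}.pdb"
    dcd_path = outdir / f"{prefix}.dcd"
    u.atoms.positions = traj.positions[0]
    u.dimensions = dims
    with warnings.catch_warnings():
        # the minimal ion topology legitimately lacks PDB-specific attrs
        warnings.filterwarnings("ignore", message="Found no information for attr")
        warnings.filterwarnings("ignore", message="Found missing chainIDs")
        u.atoms.write(str(pdb_path))
        with mda.Writer(str(dcd_path), traj.n_atoms) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.positions[f]
                u.dimensions = dims
                w.write(u.atoms)
    json_path = outdir / f"{prefix}.json"
    json_path.write_text(scene.to_json())
    return {"topology": pdb_path, "trajectory": dcd_path, "descriptor": json_path}
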