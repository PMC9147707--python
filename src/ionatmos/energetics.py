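"""Per-particle electrostatics by Ewald summation and Lennard-Jones
energy decomposition with pair-specific parameter overrides.

Electrostatics use the classic Ewald split for an orthorhombic periodic
box: the pair potential is

    psi(r) = erfc(alpha r)/r  +  (4 pi / V) sum_k  exp(-k^2/4 alpha^2)/k^2 cos(k.r)

with the Coulomb constant 332.0637 kcal Å/(mol e^2), and the self-image
constant psi_0 = (4 pi / V) sum_k f(k) - 2 alpha / sqrt(pi) giving each
particle's interaction with its own periodic images (q_i^2 psi_0, in the
kcal/mol convention including the factor C).  Alpha is set by the standard
error-balance heuristic from the real-space cutoff and the k-space extent
grows until the reciprocal tail bound passes the accuracy target.

The Lennard-Jones part uses the epsilon/r_min parameterization
U = eps [ (rmin/r)^12 - 2 (rmin/r)^6 ] with Lorentz–Berthelot combination
unless a pair-specific override (NBFIX-style) is declared, and a plain
12 Å truncation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erfc

from .core import TrajectoryEnsemble, minimum_image
from .geometry import GridSpec

COULOMB = 332.0637  # kcal Å / (mol e^2)


@dataclass
class ChargeSystem:
    """Point charges in an orthorhombic periodic box with group labels."""

    positions: np.ndarray  # (N, 3) Å
    charges: np.ndarray  # (N,) e
    box: np.ndarray  # (3,) Å
    labels: np.ndarray  # (N,) str group labels (dna1, dna2, na, cl, ...)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).reshape(-1)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.labels = np.asarray(self.labels, dtype=object).reshape(-1)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if len(self.charges) != len(self.positions) or len(self.labels) != len(
            self.positions
        ):
            raise ValueError("positions, charges and labels must align")
        self.positions = np.mod(self.positions, self.box)

    def group(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def indices_of(self, labels) -> np.ndarray:
        if isinstance(labels, str):
            labels = (labels,)
        return np.flatnonzero(np.isin(self.labels, list(labels)))

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


class EwaldConvergenceError(RuntimeError):
    pass


@dataclass
class _EwaldSetup:
    alpha: float
    kvecs: np.ndarray  # (K, 3), half space
    fk: np.ndarray  # (K,) exp(-k^2/4a^2)/k^2
    volume: float
    psi0: float  # self-image constant (without C q^2 factor)


def _ewald_setup(
    box: np.ndarray,
    alpha: float | None = None,
    kmax: int | None = None,
    accuracy: float = 1e-4,
) -> _EwaldSetup:
    box = np.asarray(box, dtype=float)
    V = float(np.prod(box))
    r_cut = float(np.min(box)) / 2.0
    if alpha is None:
        # erfc(alpha r_cut)/r_cut ~ accuracy  ->  alpha = s / r_cut
        s = 3.0
        while math.erfc(s) / r_cut > accuracy * 1e-2 and s < 8.0:
            s += 0.25
        alpha = s / r_cut
    s_eff = alpha * r_cut
    if kmax is None:
        k_cut = 2.0 * alpha * s_eff
        kmax_vec = np.maximum(
            1, np.ceil(k_cut * box / (2.0 * np.pi)).astype(int)
        )
    else:
        kmax_vec = np.full(3, int(kmax))
        k_cut = 2.0 * np.pi * float(kmax) / float(np.max(box))
    # reciprocal tail check: the largest retained Gaussian factor at the
    # boundary must be below the accuracy target
    tail = math.exp(-(k_cut**2) / (4.0 * alpha**2)) / max(k_cut**2, 1e-12)
    tail_energy = COULOMB * (4.0 * np.pi / V) * tail * k_cut**2  # rough bound
    if kmax is not None and tail_energy > accuracy:
        raise EwaldConvergenceError(
            f"kmax={kmax} too small: reciprocal tail estimate "
            f"{tail_energy:.2e} kcal/mol exceeds the accuracy target {accuracy}"
        )
    nx, ny, nz = (int(k) for k in kmax_vec)
    ks = []
    for ix in range(0, nx + 1):
        jy0 = -ny if ix > 0 else 0
        for jy in range(jy0, ny + 1):
            kz0 = -nz if (ix > 0 or jy > 0) else 1
            for kz in range(kz0, nz + 1):
                ks.append((ix, jy, kz))
    ks = np.asarray(ks, dtype=float)
    kvecs = 2.0 * np.pi * ks / box
    k2 = np.sum(kvecs**2, axis=1)
    keep = k2 <= k_cut**2 * 1.0000001
    kvecs, k2 = kvecs[keep], k2[keep]
    fk = np.exp(-k2 / (4.0 * alpha**2)) / k2
    psi0 = (4.0 * np.pi / V) * 2.0 * float(np.sum(fk)) - 2.0 * alpha / math.sqrt(
        np.pi
    )
    return _EwaldSetup(alpha, kvecs, fk, V, psi0)


def ewald_per_particle_energy(
    system: ChargeSystem,
    subject,
    partners,
    alpha: float | None = None,
    kmax: int | None = None,
    accuracy: float = 1e-4,
    self_images: str | bool = "auto",
) -> np.ndarray:
    """Ewald interaction energy of each subject particle with the partners.

    ``subject`` and ``partners`` are group labels (str or sequence of str)
    or index arrays.  The energy of subject i is sum over partner j != i of
    C q_i q_j psi(r_ij), plus the self-image term C q_i^2 psi_0 when the
    subject's own periodic images count as partners (``self_images=True``,
    or ``"auto"`` when the subject's group label is among the partner
    labels).  With that bookkeeping, summing a particle's energy over a
    partition of the partner set reproduces its energy against the union.
    Requires an overall neutral system.
    """
    if abs(system.total_charge) > 1e-8:
        raise ValueError(
            f"system has net charge {system.total_charge}; Ewald energies "
            "require a neutral full system"
        )
    if isinstance(subject, (str, tuple, list)) and not isinstance(
        subject, np.ndarray
    ):
        sub_idx = system.indices_of(subject)
        sub_labels = {subject} if isinstance(subject, str) else set(subject)
    else:
        sub_idx = np.asarray(subject, dtype=int)
        sub_labels = set(np.unique(system.labels[sub_idx]))
    if isinstance(partners, (str, tuple, list)) and not isinstance(
        partners, np.ndarray
    ):
        par_idx = system.indices_of(partners)
        par_labels = {partners} if isinstance(partners, str) else set(partners)
    else:
        par_idx = np.asarray(partners, dtype=int)
        par_labels = set(np.unique(system.labels[par_idx]))
    if self_images == "auto":
        include_self = bool(sub_labels & par_labels)
    else:
        include_self = bool(self_images)

    setup = _ewald_setup(system.box, alpha, kmax, accuracy)
    pos, q, box = system.positions, system.charges, system.box
    in_partners = np.zeros(len(q), dtype=bool)
    in_partners[par_idx] = True

    # real space: minimum image suffices (erfc negligible beyond L/2)
    energies = np.zeros(len(sub_idx))
    p_pos, p_q = pos[par_idx], q[par_idx]
    # reciprocal space: partner structure factor on the half k-space
    phase_p = setup.kvecs @ p_pos.T  # (K, Np)
    S_re = (np.cos(phase_p) * p_q).sum(axis=1)
    S_im = (np.sin(phase_p) * p_q).sum(axis=1)

    chunk = max(1, int(2e6 / max(len(par_idx), 1)))
    for c0 in range(0, len(sub_idx), chunk):
        idx = sub_idx[c0 : c0 + chunk]
        delta = minimum_image(pos[idx][:, None, :] - p_pos[None, :, :], box)
        r = np.linalg.norm(delta, axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            real = erfc(setup.alpha * r) / r
        self_mask = r < 1e-9  # the subject itself when it is in the partner set
        real[self_mask] = 0.0
        e_real = COULOMB * q[idx] * (real * p_q[None, :]).sum(axis=1)

        phase_s = setup.kvecs @ pos[idx].T  # (K, ns)
        cross = np.cos(phase_s) * S_re[:, None] + np.sin(phase_s) * S_im[:, None]
        e_rec = (
            COULOMB
            * (4.0 * np.pi / setup.volume)
            * q[idx]
            * 2.0
            * (setup.fk[:, None] * cross).sum(axis=0)
        )
        # remove the j == i reciprocal contribution for subjects inside the
        # partner set (it belongs to the self-image term, not a pair)
        own = in_partners[idx]
        e_rec -= (
            COULOMB
            * (4.0 * np.pi / setup.volume)
            * 2.0
            * float(np.sum(setup.fk))
            * q[idx] ** 2
            * own
        )
        energies[c0 : c0 + chunk] = e_real + e_rec
    if include_self:
        energies += COULOMB * q[sub_idx] ** 2 * setup.psi0
    return energies


def ewald_total_energy(
    system: ChargeSystem,
    alpha: float | None = None,
    kmax: int | None = None,
    accuracy: float = 1e-4,
) -> float:
    """Total electrostatic energy of the periodic cell (kcal/mol)."""
    all_idx = np.arange(len(system.charges))
    per = ewald_per_particle_energy(
        system, all_idx, all_idx, alpha, kmax, accuracy, self_images=True
    )
    return 0.5 * float(per.sum())


def voxel_energy_map(
    traj: TrajectoryEnsemble,
    charges: dict,
    grid: GridSpec,
    subject: str = "na",
    partner_groups=("dna1", "dna2", "na"),
    frame_stride: int = 1,
    accuracy: float = 1e-4,
):
    """Occupancy-weighted mean per-ion Ewald energy per voxel.

    ``charges`` maps each group name to its per-particle charge (e).  For
    every analyzed frame each subject ion's Ewald energy against the
    partner groups is deposited at the ion's voxel; empty voxels carry no
    value (NaN), not zero.  Returns (energy GridField, occupancy GridField)
    with across-frame SD in the occupancy field's companion column.
    """
    from .density import GridField

    groups = set(charges)
    missing = [g for g in groups if g not in traj.groups]
    if missing:
        raise ValueError(f"trajectory is missing charged groups: {missing}")
    n_frames = traj.n_frames
    e_sum = np.zeros(grid.n_points)
    e_sum2 = np.zeros(grid.n_points)
    occ = np.zeros(grid.n_points)
    labels = np.empty(traj.n_atoms, dtype=object)
    qvec = np.zeros(traj.n_atoms)
    keep = np.zeros(traj.n_atoms, dtype=bool)
    for g, qg in charges.items():
        idx = traj.groups[g]
        labels[idx] = g
        qvec[idx] = qg
        keep[idx] = True
    keep_idx = np.flatnonzero(keep)
    for f in range(0, n_frames, frame_stride):
        sysf = ChargeSystem(
            traj.positions[f, keep_idx], qvec[keep_idx], traj.box, labels[keep_idx]
        )
        e = ewald_per_particle_energy(
            sysf, subject, tuple(partner_groups), accuracy=accuracy
        )
        ion_pos = sysf.positions[sysf.group(subject)]
        flat, mask = grid.voxel_index(ion_pos)
        np.add.at(e_sum, flat[mask], e[mask])
        np.add.at(e_sum2, flat[mask], e[mask] ** 2)
        np.add.at(occ, flat[mask], 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = e_sum / occ
        var = e_sum2 / occ - mean**2
    mean[occ == 0] = np.nan
    sd = np.sqrt(np.maximum(var, 0.0))
    sd[occ == 0] = np.nan
    energy = GridField(grid, mean, occ, role="energy")
    spread = GridField(grid, sd, occ, role="energy_sd")
    return energy, spread


# ---------------------------------------------------------------------------
# Lennard-Jones


@dataclass
class LJParameterSet:
    """Per-type epsilon (kcal/mol) and rmin/2 (Å) with pair overrides."""

    types: dict  # type -> (epsilon, rmin_half)
    pair_overrides: dict = field(default_factory=dict)  # (a, b) -> (eps, rmin)
    cutoff: float = 12.0

    def __post_init__(self) -> None:
        for t, (eps, rh) in self.types.items():
            if eps < 0 or rh <= 0:
                raise ValueError(f"invalid LJ parameters for type {t!r}")
        norm = {}
        for (a, b), v in self.pair_overrides.items():
            norm[tuple(sorted((a, b)))] = v
        self.pair_overrides = norm

    def pair(self, a: str, b: str) -> tuple[float, float]:
        key = tuple(sorted((a, b)))
        if key in self.pair_overrides:
            return self.pair_overrides[key]
        try:
            ea, ra = self.types[a]
            eb, rb = self.types[b]
        except KeyError as exc:
            raise KeyError(f"missing LJ parameters for type {exc.args[0]!r}") from None
        return math.sqrt(ea * eb), ra + rb  # Lorentz–Berthelot, rmin = ra/2+rb/2 sums

    @classmethod
    def from_file(cls, path, cutoff: float = 12.0) -> "LJParameterSet":
        """Plain-text key-value reader.

        Lines: ``type NAME epsilon rmin_half`` or
        ``pair NAME1 NAME2 epsilon rmin``; '#' comments.  This also covers
        the NONBONDED/NBFIX columns of standard force-field parameter
        files once reduced to these fields.
        """
        types, overrides = {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                tok = line.split()
                if tok[0].lower() == "type" and len(tok) == 4:
                    types[tok[1]] = (float(tok[2]), float(tok[3]))
                elif tok[0].lower() == "pair" and len(tok) == 5:
                    overrides[(tok[1], tok[2])] = (float(tok[3]), float(tok[4]))
                else:
                    raise ValueError(f"unparseable LJ parameter line: {line!r}")
        return cls(types, overrides, cutoff)


def _lj_pair_energy(r: np.ndarray, eps: float, rmin: float, cutoff: float):
    x6 = (rmin / r) ** 6
    e = eps * (x6**2 - 2.0 * x6)
    e[r > cutoff] = 0.0
    return e


def lj_group_pair_energy(
    positions: np.ndarray,
    types: np.ndarray,
    box: np.ndarray,
    params: LJParameterSet,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
) -> float:
    """Total 12-6 energy between two index groups (minimum image, plain cutoff)."""
    pos = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    same = idx_a is idx_b or (
        len(idx_a) == len(idx_b) and np.array_equal(idx_a, idx_b)
    )
    total = 0.0
    ta, tb = types[idx_a], types[idx_b]
    delta = minimum_image(pos[idx_a][:, None, :] - pos[idx_b][None, :, :], box)
    r = np.linalg.norm(delta, axis=2)
    for a_t in np.unique(ta):
        for b_t in np.unique(tb):
            eps, rmin = params.pair(a_t, b_t)
            sel = np.outer(ta == a_t, tb == b_t)
            rr = r[sel]
            ok = (rr > 1e-9) & (rr <= params.cutoff)
            if eps == 0 or not np.any(ok):
                continue
            x6 = (rmin / rr[ok]) ** 6
            total += float(np.sum(eps * (x6**2 - 2.0 * x6)))
    return 0.5 * total if same else total


def lj_decomposition(
    positions: np.ndarray,
    types: np.ndarray,
    groups: dict,
    box: np.ndarray,
    params: LJParameterSet,
) -> pd.DataFrame:
    """Additive group-pair LJ decomposition of one frame.

    ``groups`` maps names (dna1, dna2, na, ...) to index arrays.  Returns a
    table of E_LJ per unordered group pair (self pairs included) plus a
    ``total`` row equal to their sum.
    """
    types = np.asarray(types, dtype=object)
    names = sorted(groups)
    rows = []
    total = 0.0
    for i, a in enumerate(names):
        for b in names[i:]:
            e = lj_group_pair_energy(
                positions, types, box, params, groups[a], groups[b]
            )
            rows.append({"pair": f"{a}-{b}", "E_LJ": e})
            total += e
    rows.append({"pair": "total", "E_LJ": total})
    return pd.DataFrame(rows)


def lj_difference(table_flexible: pd.DataFrame, table_rigid: pd.DataFrame):
    """Delta E_LJ = E(flexible) - E(rigid) per group pair."""
    merged = table_flexible.merge(
        table_rigid, on="pair", suffixes=("_flexible", "_rigid")
    )
    merged["delta_E_LJ"] = merged["E_LJ_flexible"] - merged["E_LJ_rigid"]
    return merged
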