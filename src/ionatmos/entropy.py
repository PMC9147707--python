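"""Differential entropy of ion-density fluctuations.

Density fluctuations in small volumes are treated as multivariate Gaussian;
the differential entropy of an N-point Gaussian is a constant (depending on
grid spacing and point count) plus half the log-determinant of the
covariance of the density fluctuations, in units of k_B.  Because the
constant cancels when two systems are evaluated on identical point sets,
the flexible-minus-rigid difference

    dS = S(flexible) - S(rigid) = (1/2) [ln|Sigma_flex| - ln|Sigma_rigid|]

is well defined and unit-free.  The standard error of dS is estimated by a
jackknife over nine contiguous time blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CovarianceModel:
    """Sample covariance of density fluctuations at a set of points."""

    sigma: np.ndarray  # (P, P), Å^-6
    mean: np.ndarray  # (P,), Å^-3
    n_frames: int
    ridge: float = 0.0  # Å^-6 added to the diagonal
    constant_points: np.ndarray = field(default=None)  # flags of zero-variance points

    @property
    def n_points(self) -> int:
        return self.sigma.shape[0]


@dataclass
class EntropyResult:
    """Entropy up to the additive constant, in k_B."""

    S_rel: float
    region: str = ""
    standard_error: float = 0.0


def density_covariance(
    series, ridge_scale: float = 1e-3, ridge: float | None = None
) -> CovarianceModel:
    """Unbiased sample covariance of density fluctuations.

    ``series`` is frames x points (DataFrame or array).  A ridge eps*I is
    added only when the smallest eigenvalue falls below the floor
    ``ridge_scale * median(diag Sigma)`` (or the explicit ``ridge``);
    the amount added is recorded.  Points with zero variance (constant
    series) are flagged but the covariance is still returned, ridged.
    """
    data = np.asarray(series, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    n_frames, n_points = data.shape
    if n_frames < 2:
        raise ValueError("need at least 2 frames to estimate a covariance")
    mean = data.mean(axis=0)
    delta = data - mean
    sigma = delta.T @ delta / (n_frames - 1)
    sigma = 0.5 * (sigma + sigma.T)
    constant = np.isclose(np.diag(sigma), 0.0)
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} point(s) have constant density series"
        )
    diag_med = float(np.median(np.diag(sigma)))
    floor = ridge if ridge is not None else ridge_scale * max(diag_med, 0.0)
    min_eig = float(np.linalg.eigvalsh(sigma)[0])
    applied = 0.0
    if floor > 0 and min_eig < floor:
        applied = floor
        sigma = sigma + applied * np.eye(n_points)
    return CovarianceModel(sigma, mean, n_frames, applied, constant)


def differential_entropy(cov: CovarianceModel, region: str = "") -> EntropyResult:
    """S_rel = (1/2) ln|Sigma| in k_B, via a stable log-determinant."""
    sign, logdet = np.linalg.slogdet(cov.sigma)
    if sign <= 0:
        eig = np.linalg.eigvalsh(cov.sigma)
        raise ValueError(
            f"covariance is not positive definite after ridge {cov.ridge}: "
            f"smallest eigenvalue {eig[0]:.3e}"
        )
    return EntropyResult(0.5 * logdet, region=region)


@dataclass
class EntropyDifference:
    """dS = S(flexible) - S(rigid) with jackknife standard error."""

    delta_S: float
    standard_error: float
    S_flexible: float
    S_rigid: float
    region: str
    n_points: int
    n_frames: int
    ridge_flexible: float
    ridge_rigid: float

    def to_frame(self, d_separation: float | None = None) -> pd.DataFrame:
        row = {
            "region": self.region,
            "delta_S_kB": self.delta_S,
            "se_kB": self.standard_error,
            "n_points": self.n_points,
            "n_frames": self.n_frames,
            "ridge_flexible": self.ridge_flexible,
            "ridge_rigid": self.ridge_rigid,
        }
        if d_separation is not None:
            row["d"] = d_separation
        return pd.DataFrame([row])


def _s_rel(data: np.ndarray, ridge_scale: float, ridge: float | None) -> tuple:
    cov = density_covariance(data, ridge_scale=ridge_scale, ridge=ridge)
    return differential_entropy(cov).S_rel, cov.ridge


def entropy_difference(
    series_flexible,
    series_rigid,
    region: str = "",
    n_blocks: int = 9,
    ridge_scale: float = 1e-3,
    ridge: float | None = None,
) -> EntropyDifference:
    """Entropy difference between two systems on identical point sets.

    Both series must have the same number of points (columns); mismatched
    point sets are rejected rather than silently subsampled, because the
    additive constant only cancels on matched grids.  The standard error is
    a delete-one jackknife over ``n_blocks`` contiguous time blocks,
    recomputing dS on each leave-one-out subset.
    """
    a = np.asarray(series_flexible, dtype=float)
    b = np.asarray(series_rigid, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"point sets differ ({a.shape[1]} vs {b.shape[1]}); the entropy "
            "constant only cancels on identical point sets"
        )
    s_flex, ridge_f = _s_rel(a, ridge_scale, ridge)
    s_rig, ridge_r = _s_rel(b, ridge_scale, ridge)
    delta = s_flex - s_rig

    n = min(a.shape[0], b.shape[0])
    blocks = min(n_blocks, n // 2)
    se = 0.0
    if blocks >= 2:
        edges_a = np.linspace(0, a.shape[0], blocks + 1, dtype=int)
        edges_b = np.linspace(0, b.shape[0], blocks + 1, dtype=int)
        reps = []
        for k in range(blocks):
            keep_a = np.r_[0 : edges_a[k], edges_a[k + 1] : a.shape[0]]
            keep_b = np.r_[0 : edges_b[k], edges_b[k + 1] : b.shape[0]]
            sa, _ = _s_rel(a[keep_a], ridge_scale, ridge)
            sb, _ = _s_rel(b[keep_b], ridge_scale, ridge)
            reps.append(sa - sb)
        reps = np.asarray(reps)
        se = float(
            np.sqrt((blocks - 1) / blocks * np.sum((reps - reps.mean()) ** 2))
        )
    return EntropyDifference(
        delta_S=float(delta),
        standard_error=se,
        S_flexible=float(s_flex),
        S_rigid=float(s_rig),
        region=region,
        n_points=a.shape[1],
        n_frames=min(a.shape[0], b.shape[0]),
        ridge_flexible=ridge_f,
        ridge_rigid=ridge_r,
    )
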