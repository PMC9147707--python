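"""PMF assembly from mean-force samples along the interhelical distance.

Instantaneous force samples are accumulated in half-open 0.1 Å bins over
[21, 31] Å, consecutive non-overlapping windows are stitched, and the PMF
is the trapezoid integral of the negative binned mean force anchored to
zero at the largest-distance bin.  Convergence diagnostics report per-bin
normality (Anderson–Darling at a configured level), sampling uniformity
(min/median bin-count ratio) and a block-variance force SE propagated
through the integral to a per-bin PMF uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_RANGE = (21.0, 31.0)
DEFAULT_BIN_WIDTH = 0.1


@dataclass
class BinnedForces:
    """Per-bin force statistics; bins are half-open [lo, lo + w)."""

    bin_centers: np.ndarray
    counts: np.ndarray
    means: np.ndarray
    variances: np.ndarray  # sample variance (ddof=1), NaN where count < 2
    bin_width: float
    range: tuple[float, float]
    n_dropped: int = 0
    samples: list = field(default_factory=list)  # per-bin sample arrays, time order

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


@dataclass
class PMFProfile:
    """Integrated free-energy profile with per-bin uncertainty."""

    bin_centers: np.ndarray
    mean_force: np.ndarray  # kcal/(mol Å)
    n_samples: np.ndarray
    pmf: np.ndarray  # kcal/mol, 0 at the anchor (largest-d bin)
    uncertainty: np.ndarray  # kcal/mol
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d": self.bin_centers,
                "mean_force": self.mean_force,
                "n_samples": self.n_samples,
                "pmf": self.pmf,
                "uncertainty": self.uncertainty,
            }
        )


def accumulate_bins(
    samples: pd.DataFrame,
    bin_width: float = DEFAULT_BIN_WIDTH,
    d_range: tuple[float, float] = DEFAULT_RANGE,
) -> BinnedForces:
    """Bin (d, force) samples into half-open 0.1 Å bins.

    Samples outside the range are counted and dropped.  Raises when no
    sample falls in range.
    """
    lo, hi = d_range
    d = np.asarray(samples["d"], dtype=float)
    f = np.asarray(samples["force"], dtype=float)
    inside = (d >= lo) & (d < hi)
    n_dropped = int((~inside).sum())
    if not np.any(inside):
        raise ValueError("no force samples inside the requested range")
    d, f = d[inside], f[inside]
    n_bins = int(round((hi - lo) / bin_width))
    idx = np.floor((d - lo) / bin_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    centers = lo + bin_width * (np.arange(n_bins) + 0.5)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=f, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    sq = np.bincount(idx, weights=f**2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        variances = (sq - counts * means**2) / (counts - 1)
    variances[counts < 2] = np.nan
    order = np.argsort(idx, kind="stable")  # keeps time order inside bins
    sorted_idx = idx[order]
    sorted_f = f[order]
    bounds = np.searchsorted(sorted_idx, np.arange(n_bins + 1))
    per_bin = [sorted_f[bounds[k] : bounds[k + 1]] for k in range(n_bins)]
    return BinnedForces(
        centers, counts, means, variances, bin_width, (lo, hi), n_dropped, per_bin
    )


def stitch_windows(windows: list[BinnedForces]) -> BinnedForces:
    """Concatenate consecutive, non-overlapping force windows.

    Windows must tile the overall range without gaps or overlaps (at the
    bin-width tolerance).  Force-level concatenation needs no offset; a
    PMF-level join is handled by :func:`stitch_pmf_profiles`.
    """
    if not windows:
        raise ValueError("no windows")
    ws = sorted(windows, key=lambda w: w.range[0])
    for a, b in zip(ws, ws[1:]):
        if abs(a.range[1] - b.range[0]) > 1e-9:
            raise ValueError(
                f"windows do not tile: [{a.range[0]}, {a.range[1]}] then "
                f"[{b.range[0]}, {b.range[1]}]"
            )
        if abs(a.bin_width - b.bin_width) > 1e-12:
            raise ValueError("windows must share a bin width")
    return BinnedForces(
        np.concatenate([w.bin_centers for w in ws]),
        np.concatenate([w.counts for w in ws]),
        np.concatenate([w.means for w in ws]),
        np.concatenate([w.variances for w in ws]),
        ws[0].bin_width,
        (ws[0].range[0], ws[-1].range[1]),
        sum(w.n_dropped for w in ws),
        [s for w in ws for s in w.samples],
    )


def stitch_pmf_profiles(profiles: list[PMFProfile]) -> PMFProfile:
    """Join PMF-level windows, offset-matching at shared boundaries.

    Each profile's integration constant is shifted so that consecutive
    windows agree at the adjoining bins; the stitched profile is then
    re-anchored to 0 at its largest-d bin.
    """
    ps = sorted(profiles, key=lambda p: p.bin_centers[0])
    out_c = [ps[-1].bin_centers]
    out_f = [ps[-1].mean_force]
    out_n = [ps[-1].n_samples]
    out_p = [ps[-1].pmf]
    out_u = [ps[-1].uncertainty]
    for p in reversed(ps[:-1]):
        # match this window's last bin to the next window's first by
        # extrapolating the join with the trapezoid step between them
        right_c = out_c[0][0]
        right_p = out_p[0][0]
        gap = right_c - p.bin_centers[-1]
        slope = -0.5 * (p.mean_force[-1] + out_f[0][0])
        target = right_p - slope * gap
        shifted = p.pmf - p.pmf[-1] + target
        out_c.insert(0, p.bin_centers)
        out_f.insert(0, p.mean_force)
        out_n.insert(0, p.n_samples)
        out_p.insert(0, shifted)
        out_u.insert(0, p.uncertainty)
    pmf = np.concatenate(out_p)
    pmf = pmf - pmf[-1]
    return PMFProfile(
        np.concatenate(out_c),
        np.concatenate(out_f),
        np.concatenate(out_n),
        pmf,
        np.concatenate(out_u),
    )


def integrate_pmf(
    binned: BinnedForces,
    min_samples: int = 1,
    bin_se: np.ndarray | None = None,
    anchor: str = "max_d",
) -> PMFProfile:
    """Trapezoid integral of the negative mean force from the anchor bin.

    The anchor (largest-d bin by default, as the free-energy zero) gets PMF
    exactly 0.  Every bin must carry at least ``min_samples`` samples (bins
    below the minimum are listed in the error; there is no silent
    interpolation).  Per-bin PMF uncertainty propagates the per-bin force
    SEs (``bin_se`` if given, else sqrt(var/n)) through the trapezoid
    weights assuming independent bins, so it is non-decreasing away from
    the anchor.
    """
    if anchor not in ("max_d", "min_d"):
        raise ValueError("anchor must be 'max_d' or 'min_d'")
    low = np.flatnonzero(binned.counts < min_samples)
    if low.size:
        raise ValueError(
            "bins below the minimum sample count: "
            + ", ".join(f"{binned.bin_centers[k]:.2f}" for k in low)
        )
    c = binned.bin_centers
    f = binned.means
    w = binned.bin_width
    n = len(c)
    pmf = np.zeros(n)
    if anchor == "max_d":
        for k in range(n - 2, -1, -1):
            pmf[k] = pmf[k + 1] + 0.5 * (f[k] + f[k + 1]) * w
    else:
        for k in range(1, n):
            pmf[k] = pmf[k - 1] - 0.5 * (f[k] + f[k - 1]) * w
    if bin_se is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            bin_se = np.sqrt(
                np.where(binned.counts > 1, binned.variances, 0.0)
                / np.maximum(binned.counts, 1)
            )
        bin_se = np.nan_to_num(bin_se)
    # trapezoid weight of bin k in the integral from the anchor to bin j:
    # w for interior bins, w/2 at both ends
    var = np.zeros(n)
    if anchor == "max_d":
        for k in range(n - 2, -1, -1):
            weights = np.full(n - k, w)
            weights[0] = weights[-1] = 0.5 * w
            var[k] = float(np.sum((weights * bin_se[k:]) ** 2))
    else:
        for k in range(1, n):
            weights = np.full(k + 1, w)
            weights[0] = weights[-1] = 0.5 * w
            var[k] = float(np.sum((weights * bin_se[: k + 1]) ** 2))
    return PMFProfile(c, f, binned.counts.copy(), pmf, np.sqrt(var))


def convergence_diagnostics(
    binned: BinnedForces,
    n_blocks: int = 9,
    normality_level: float = 0.05,
) -> dict:
    """Per-bin normality, sampling uniformity and block-variance force SE.

    Normality uses the Anderson–Darling statistic against the per-bin
    critical value at ``normality_level``; uniformity is the min/median
    bin-count ratio; the per-bin SE comes from the variance of block means
    over ``n_blocks`` contiguous blocks of each bin's sample stream,
    propagated by :func:`integrate_pmf` into PMF uncertainty.
    """
    n = binned.n_bins
    normal_ok = np.zeros(n, dtype=bool)
    ad_stat = np.full(n, np.nan)
    block_se = np.full(n, np.nan)
    sparse = np.zeros(n, dtype=bool)
    level_pct = normality_level * 100.0
    for k in range(n):
        s = binned.samples[k] if k < len(binned.samples) else np.empty(0)
        if len(s) < 8:
            sparse[k] = True
            continue
        try:
            res = stats.anderson(s, dist="norm", method="interpolate")
            ad_stat[k] = res.statistic
            normal_ok[k] = res.pvalue > normality_level
        except TypeError:  # older scipy: critical-value interface
            res = stats.anderson(s, dist="norm")
            ad_stat[k] = res.statistic
            crit = dict(zip(res.significance_level, res.critical_values))
            cv = crit.get(level_pct, res.critical_values[2])
            normal_ok[k] = res.statistic < cv
        blocks = min(n_blocks, len(s) // 2)
        if blocks >= 2:
            edges = np.linspace(0, len(s), blocks + 1, dtype=int)
            bm = np.array([s[edges[i] : edges[i + 1]].mean() for i in range(blocks)])
            block_se[k] = bm.std(ddof=1) / np.sqrt(blocks)
    counts = binned.counts
    uniformity = float(np.min(counts) / np.median(counts)) if np.median(counts) else 0.0
    return {
        "normality_pass": normal_ok,
        "normality_statistic": ad_stat,
        "normality_level": normality_level,
        "fraction_normal": float(np.mean(normal_ok[~sparse])) if np.any(~sparse) else 0.0,
        "uniformity": uniformity,
        "block_se": block_se,
        "sparse_bins": sparse,
        "n_blocks": n_blocks,
    }


# ---------------------------------------------------------------------------
# readers


def read_force_table(path, d_col: str = "d", force_col: str = "force"):
    """CSV/TSV force-sample reader with (d, force[, time]) columns."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return df.rename(columns={d_col: "d", force_col: "force"})


def read_colvars_traj(path, d_col: int = 1, force_col: int = 2):
    """Column-oriented plain-text reader for Colvars-style traj output.

    Skips '#'-commented header lines; columns are whitespace separated with
    step, colvar value, applied/system force.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.lstrip().startswith("#") or not line.strip():
                continue
            tok = line.split()
            rows.append((float(tok[d_col]), float(tok[force_col])))
    return pd.DataFrame(rows, columns=["d", "force"])
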