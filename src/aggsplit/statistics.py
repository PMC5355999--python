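"""Size-distribution fitting, ensemble statistics and derived quantities.

Aggregate sizes A* in a single frame follow a left-truncated exponential
law; the fitted mean is reported in the MV[LB, UB] convention, where a
bound replaced by a truncation value is marked primed.  Frame means are
summarized over time by their mean, their SD over frames, and the pooled
(variance-weighted) SD of the within-frame dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import ChannelGeometry, ImageStack, StructureTable


# ---------------------------------------------------------------------------
# Truncated exponential fit


@dataclass
class SizeDistributionFit:
    """Truncated-exponential fit of an A* sample.

    ``mv = lower_trunc + 1/rate``; ``lb``/``ub`` follow the MV[LB, UB]
    notation where a truncated bound is replaced by the truncation value
    and flagged primed; ``ci_low``/``ci_high`` always hold the two-sided
    bootstrap percentile interval of the mean.
    """

    lower_trunc: float
    upper_trunc: float | None
    mv: float
    lb: float
    ub: float
    lb_primed: bool
    ub_primed: bool
    ci_low: float
    ci_high: float
    rate: float
    k: int
    method: str = "ls-log-survival+bootstrap"

    def __post_init__(self) -> None:
        if not self.lb_primed and not (self.lb <= self.mv):
            raise ValueError("lb must not exceed mv")
        if not self.ub_primed and not (self.mv <= self.ub):
            raise ValueError("ub must not fall below mv")

    def __str__(self) -> str:
        lb = f"{self.lb:.2f}" + ("'" if self.lb_primed else "")
        ub = f"{self.ub:.2f}" + ("'" if self.ub_primed else "")
        return f"{self.mv:.2f}[{lb}, {ub}]"


def _ls_rate(sorted_vals: np.ndarray, lower: float, log_surv: np.ndarray,
             weights: np.ndarray) -> float:
    """Weighted least-squares slope of log empirical survival vs (value - lower).

    Weights proportional to the survival fraction down-weight the deep
    tail, whose log-survival estimates are noisiest; the fit is exact on
    noiseless exponential data regardless of the weights.
    """
    x = sorted_vals - lower
    wsum = weights.sum()
    xm = (weights * x).sum() / wsum
    ym = (weights * log_surv).sum() / wsum
    denom = np.sum(weights * (x - xm) ** 2)
    if denom <= 0:
        raise ValueError("degenerate sample: zero variance")
    slope = np.sum(weights * (x - xm) * (log_surv - ym)) / denom
    return -slope


def fit_truncated_exponential(
    values: Sequence[float],
    lower: float = 0.5,
    upper: float | None = None,
    n_boot: int = 1000,
    seed: int | None = 0,
    min_k: int = 30,
) -> SizeDistributionFit:
    """Fit an exponential rate to values above ``lower`` (and below ``upper``).

    The rate is the least-squares slope of the log empirical survival
    fraction (Hazen plotting positions) against value - lower; the mean is
    ``lower + 1/rate``.  95% bounds come from a percentile bootstrap
    (``n_boot`` resamples); truncated bounds are reported primed, per the
    MV[LB', UB'] convention.
    """
    vals = np.asarray(values, float)
    vals = vals[vals > lower]
    if upper is not None:
        vals = vals[vals < upper]
    k = vals.size
    if k < min_k:
        raise ValueError(f"insufficient sample: k={k} < {min_k}")
    if np.ptp(vals) == 0:
        raise ValueError("degenerate sample: zero variance")
    srt = np.sort(vals)
    surv = 1.0 - (np.arange(1, k + 1) - 0.5) / k
    log_surv = np.log(surv)
    rate = _ls_rate(srt, lower, log_surv, surv)
    if rate <= 0:
        raise ValueError("degenerate sample: non-decaying survival")
    mv = lower + 1.0 / rate

    rng = np.random.default_rng(seed)
    boot_mv = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(2e6 / max(k, 1))))
    wsum = surv.sum()
    ym = (surv * log_surv).sum() / wsum
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        res = np.sort(rng.choice(vals, size=(b, k), replace=True), axis=1)
        x = res - lower
        xm = (surv * x).sum(axis=1, keepdims=True) / wsum
        num = (surv * (x - xm) * (log_surv - ym)).sum(axis=1)
        den = (surv * (x - xm) ** 2).sum(axis=1)
        boot_mv[done:done + b] = lower - den / num
        done += b
    ci_low, ci_high = np.percentile(boot_mv, [2.5, 97.5])

    lb, lb_primed = (lower, True) if lower > 0 else (float(ci_low), False)
    if upper is not None:
        ub, ub_primed = upper, True
    else:
        ub, ub_primed = float(ci_high), False
    return SizeDistributionFit(
        lower_trunc=lower, upper_trunc=upper, mv=float(mv), lb=lb, ub=ub,
        lb_primed=lb_primed, ub_primed=ub_primed, ci_low=float(ci_low),
        ci_high=float(ci_high), rate=float(rate), k=int(k),
    )


# ---------------------------------------------------------------------------
# Per-frame and ensemble statistics


def frame_stats(table: StructureTable, frame_index: int):
    """(mean A*, SD of A*, count) for one frame; None if the frame is empty.

    For exponentially distributed in-frame areas the SD approaches the
    untruncated mean, so mean and SD carry the same scale.
    """
    sub = table.records[table.records["frame_index"] == frame_index]
    if len(sub) == 0:
        return None
    a = sub["area_norm"].to_numpy()
    return float(a.mean()), float(a.std(ddof=0)), int(a.size)


@dataclass
class EnsembleStats:
    """Time-ensemble summary of per-frame means."""

    n_frames: int
    mean_over_frames: float
    sd_over_frames: float
    pooled_sd: float
    k_total: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one non-empty frame")
        if min(self.sd_over_frames, self.pooled_sd) < 0:
            raise ValueError("dispersions must be >= 0")


def ensemble_stats(per_frame: Sequence[tuple]) -> EnsembleStats:
    """Combine per-frame (mean, sd, k) tuples.

    ``pooled_sd`` is the variance-weighted pooled estimate
    sqrt( sum (k_i - 1) s_i^2 / sum (k_i - 1) ); frames with k = 1
    contribute nothing to it.
    """
    per_frame = [t for t in per_frame if t is not None]
    if not per_frame:
        raise ValueError("all frames empty")
    means = np.array([t[0] for t in per_frame])
    sds = np.array([t[1] for t in per_frame])
    ks = np.array([t[2] for t in per_frame])
    dof = ks - 1
    pooled = float(np.sqrt(np.sum(dof * sds**2) / dof.sum())) if dof.sum() > 0 else float(sds.mean())
    return EnsembleStats(
        n_frames=len(per_frame),
        mean_over_frames=float(means.mean()),
        sd_over_frames=float(means.std(ddof=0)),
        pooled_sd=pooled,
        k_total=int(ks.sum()),
    )


def stats_for_branch(table: StructureTable, branch: str) -> EnsembleStats:
    """Ensemble stats over all frames for one branch of the junction."""
    sub = table.records[table.records["branch"] == branch]
    per_frame = []
    for fi, grp in sub.groupby("frame_index"):
        a = grp["area_norm"].to_numpy()
        per_frame.append((float(a.mean()), float(a.std(ddof=0)), int(a.size)))
    return ensemble_stats(per_frame)


def normalize_to_parent(daughter: EnsembleStats, parent: EnsembleStats):
    """Daughter/parent ratio of mean A* with propagated uncertainty."""
    if parent.mean_over_frames <= 0:
        raise ValueError("parent mean must be positive")
    ratio = daughter.mean_over_frames / parent.mean_over_frames
    rel = np.sqrt(
        (daughter.sd_over_frames / daughter.mean_over_frames) ** 2
        + (parent.sd_over_frames / parent.mean_over_frames) ** 2
    ) if daughter.mean_over_frames > 0 else np.nan
    return float(ratio), float(ratio * rel)


def size_flow_parameter(qstar: float, ratio: float) -> float:
    """Size-flow parameter F = Q* x (normalized mean size).

    Falls on the identity line F = Q* when daughter and parent carry the
    same mean size.
    """
    if not (0.0 <= qstar <= 1.0):
        raise ValueError("qstar must lie in [0, 1]")
    return qstar * ratio


# ---------------------------------------------------------------------------
# Spatial distributions and wall margins


@dataclass
class SpatialDistribution:
    """Histogram of the cross-flow coordinate for a branch and size range."""

    branch: str
    size_range: tuple[float, float]
    bin_edges: np.ndarray
    counts: np.ndarray
    empty: bool = False


def spatial_distribution(table: StructureTable, branch: str,
                         size_range: tuple[float, float],
                         bins: int | np.ndarray = 20) -> SpatialDistribution:
    """Cross-flow histogram of structures in a branch and A* range.

    The cross-flow coordinate is x* in the parent branch and y* in the
    daughters.
    """
    sub = table.in_branch(branch)
    lo, hi = size_range
    sub = sub[(sub["area_norm"] >= lo) & (sub["area_norm"] <= hi)]
    coord = sub["xstar"] if branch in ("parent", "junction") else sub["ystar"]
    counts, edges = np.histogram(coord.to_numpy(), bins=bins, range=(-0.5, 0.5))
    return SpatialDistribution(branch=branch, size_range=(lo, hi),
                               bin_edges=edges, counts=counts,
                               empty=len(sub) == 0)


def wall_margin_location(table: StructureTable, astar_target: float,
                         tol: float = 0.25, wall_side: str = "right",
                         branch: str = "parent", min_records: int = 100) -> float:
    """Near-wall extent x*_A of structures of one size.

    Selects parent-branch structures with |A* - target| <= tol and returns
    the mean cross-flow position of the 5% tail toward ``wall_side`` —
    the location beyond which structures of that size are essentially
    absent.
    """
    sub = table.in_branch(branch)
    sub = sub[np.abs(sub["area_norm"] - astar_target) <= tol]
    coord = (sub["xstar"] if branch in ("parent", "junction") else sub["ystar"]).to_numpy()
    if coord.size < min_records:
        raise ValueError(f"insufficient sample: {coord.size} < {min_records}")
    if wall_side == "right":
        cut = np.percentile(coord, 95.0)
        tail = coord[coord >= cut]
    elif wall_side == "left":
        cut = np.percentile(coord, 5.0)
        tail = coord[coord <= cut]
    else:
        raise ValueError("wall_side must be 'left' or 'right'")
    return float(tail.mean())


def pseudo_shear(mean_speed_um_s: float, depth_um: float) -> float:
    """Mean velocity over channel depth, in 1/s — a proxy shear level."""
    if depth_um <= 0:
        raise ValueError("depth must be positive")
    return mean_speed_um_s / depth_um


# ---------------------------------------------------------------------------
# Haematocrit profiles


@dataclass
class HaematocritProfile:
    """Haematocrit estimate across a branch width from light transmission."""

    positions_xstar: np.ndarray
    values: np.ndarray
    mapping: str
    params: dict

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("haematocrit must be >= 0")


def hct_linear(istar, alpha: float):
    """Linear intensity-to-haematocrit mapping H = alpha * (1 - I*)."""
    return alpha * (1.0 - np.asarray(istar, float))


def hct_nonlinear(istar, a: float = 0.685, b: float = 9.244):
    """Non-linear mapping H = a * (1 - I*^b).

    Monotone decreasing in I* with H(1) = 0; the algebraic form is a
    package choice around the published calibration constants (a, b).
    """
    return a * (1.0 - np.asarray(istar, float) ** b)


def hct_profile(stack: ImageStack, geometry: ChannelGeometry,
                mapping: str = "linear", params: dict | None = None,
                ystar_range: tuple[float, float] = (-2.0, -1.0),
                mapping_fn: Callable | None = None) -> HaematocritProfile:
    """Cross-flow haematocrit profile of the parent branch.

    Intensities are time-averaged over the stack and over the axial window
    ``ystar_range``, normalized by the brightest position so I* in [0, 1],
    then mapped to H by the linear or non-linear mapping (or a supplied
    monotone-decreasing ``mapping_fn``).
    """
    params = dict(params or {})
    nr, nc = geometry.frame_shape_px
    rows, cols = np.mgrid[0:nr, 0:nc]
    xs, ys = geometry.to_normalized_coords((rows, cols))
    sel = (np.abs(xs) <= 0.5) & (ys >= ystar_range[0]) & (ys <= ystar_range[1])
    if not sel.any():
        raise ValueError("axial window outside frame")
    mean_img = stack.frames.mean(axis=0)
    cols_in = np.unique(cols[sel])
    profile = np.array([mean_img[sel & (cols == c)].mean() for c in cols_in])
    xstar = geometry.to_normalized_coords((0.0, cols_in.astype(float)))[0]
    istar = profile / profile.max()
    if istar.min() < 0:
        warnings.warn("I* outside [0, 1]; clipping")
    istar = np.clip(istar, 0.0, 1.0)
    if mapping_fn is not None:
        h = np.asarray(mapping_fn(istar), float)
        mapping = "custom"
    elif mapping == "linear":
        h = hct_linear(istar, alpha=params.get("alpha", 0.3))
    elif mapping == "nonlinear":
        h = hct_nonlinear(istar, a=params.get("a", 0.685), b=params.get("b", 9.244))
    else:
        raise ValueError("mapping must be 'linear' or 'nonlinear'")
    return HaematocritProfile(positions_xstar=xstar, values=np.clip(h, 0.0, None),
                              mapping=mapping, params=params)


# ---------------------------------------------------------------------------
# Normality check


def normality_check(values: Sequence[float], level_pct: float = 5.0):
    """One-sample Anderson-Darling test against the normal family.

    Returns (statistic, reject) at the given significance level.
    """
    vals = np.asarray(values, float)
    if vals.size < 8:
        raise ValueError("need at least 8 values")
    if np.ptp(vals) == 0:
        raise ValueError("degenerate sample: zero variance")
    with warnings.catch_warnings():
        # keep the critical-value interface across scipy's API transition
        warnings.simplefilter("ignore", FutureWarning)
        res = sstats.anderson(vals, dist="norm")
    levels = list(res.significance_level)
    if level_pct not in levels:
        raise ValueError(f"level must be one of {levels}")
    crit = res.critical_values[levels.index(level_pct)]
    return float(res.statistic), bool(res.statistic > crit)
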