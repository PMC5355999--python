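"""Aggregate detection by calibrated gradient edge detection.

The pipeline follows six stages: (1) contrast enhancement and illumination
correction, (2) local intensity gradients from the four opposite-neighbour
pairs of a 3x3 window, (3) normalization by the local mean intensity,
(4) optional correction of locally blurred regions using a
coefficient-of-variation reference map, (5) binarization at a threshold
calibrated so the mean detected structure area in a non-aggregating
reference equals the characteristic single-RBC area Ac, and (6) removal of
components smaller than a fixed fraction of Ac as noise.

Normalization by the local mean makes the gradient measure invariant to
smooth illumination and to global intensity scaling, and amplifies relative
contrast inside dark (strongly absorbing) aggregates, so detected
structures are filled regions bounded by the strong edge response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import (
    ChannelGeometry,
    ImageStack,
    PipelineConfig,
    StructureTable,
    STRUCTURE_COLUMNS,
    validate_frame,
)

import pandas as pd

#: guard below which the local mean is considered undefined
LOCAL_MEAN_EPS = 1e-3


@dataclass
class GradientMap:
    """Normalized intensity-gradient magnitudes (intensity per um).

    Values are NaN where undefined (the one-pixel border ring and pixels
    whose local mean falls below the guard).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2:
            raise ValueError("gradient map must be 2-D")
        defined = np.isfinite(v)
        if defined.any() and v[defined].min() < 0:
            raise ValueError("gradient magnitudes must be >= 0")
        self.values = v


@dataclass
class CoVMap:
    """Local coefficient of variation normalized by its in-channel maximum."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)


# ---------------------------------------------------------------------------
# Stage 1: pre-processing


def enhance_contrast(frame: np.ndarray, percentiles=(0.0, 99.8),
                     mask: np.ndarray | None = None) -> np.ndarray:
    """Stretch the [p_low, p_high] percentile range (within ``mask``) to [0, 1].

    Monotone linear remap with clipping; a constant frame is returned
    unchanged with a warning.
    """
    frame = validate_frame(frame)
    sel = frame[mask] if mask is not None else frame
    if sel.max() <= sel.min():
        warnings.warn("constant frame: contrast enhancement skipped")
        return frame.copy()
    lo, hi = np.percentile(sel, percentiles)
    if hi <= lo:
        warnings.warn("degenerate percentile range: contrast enhancement skipped")
        return frame.copy()
    return np.clip((frame - lo) / (hi - lo), 0.0, 1.0)


def _gauss_plus_offset(coords, amp, r0, c0, sigma, off):
    rr, cc = coords
    return amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2)) + off


def fit_illumination(frame: np.ndarray, mask: np.ndarray | None = None,
                     max_points: int = 20000):
    """Least-squares fit of a Gaussian-plus-offset surface to bright pixels.

    Returns (params, surface) where params = (amp, row0, col0, sigma, offset)
    and surface is the fitted illumination evaluated on the full frame,
    normalized to peak 1.
    """
    frame = validate_frame(frame)
    nr, nc = frame.shape
    sel = np.ones_like(frame, bool) if mask is None else mask.copy()
    thresh = np.median(frame[sel])
    sel &= frame >= thresh  # background (bright) pixels only
    rows, cols = np.nonzero(sel)
    if rows.size < 16:
        raise RuntimeError("illumination fit failed: too few background pixels")
    stride = max(1, rows.size // max_points)
    rows, cols = rows[::stride], cols[::stride]
    vals = frame[rows, cols]
    p0 = (float(vals.max()), nr / 2.0, nc / 2.0, 0.5 * min(nr, nc), 0.0)
    try:
        popt, _ = optimize.curve_fit(
            _gauss_plus_offset, (rows.astype(float), cols.astype(float)), vals,
            p0=p0, maxfev=4000,
        )
    except (RuntimeError, ValueError) as exc:
        raise RuntimeError(f"illumination fit failed: {exc}") from exc
    amp, r0, c0, sigma, off = popt
    rr, cc = np.mgrid[0:nr, 0:nc]
    surface = _gauss_plus_offset((rr, cc), amp, r0, c0, abs(sigma), off)
    peak = surface.max()
    if peak <= 0 or not np.all(np.isfinite(surface)):
        raise RuntimeError("illumination fit failed: degenerate surface")
    return popt, surface / peak


def correct_illumination(frame: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Divide out a fitted Gaussian illumination surface and renormalize."""
    _, surface = fit_illumination(frame, mask=mask)
    out = frame / np.maximum(surface, 1e-6)
    top = out.max()
    if top > 1.0:
        out = out / top
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Stages 2-3: local gradients and normalization


def local_gradient_magnitude(frame: np.ndarray, geometry: ChannelGeometry,
                             diag_ds_um: float = 1.61) -> GradientMap:
    """Gradient magnitude from the four opposite-neighbour difference quotients.

    In each 3x3 window the four differences (E-W, N-S, NE-SW, NW-SE) are
    divided by the distance between the paired pixels — 2 x um_per_px for
    the horizontal/vertical pairs and ``diag_ds_um`` for the diagonal pairs
    — and combined as their root mean square.  The border ring is NaN.
    """
    frame = validate_frame(frame)
    if min(frame.shape) <= 3:
        raise ValueError("frame must be larger than 3x3")
    ds_hv = 2.0 * geometry.um_per_px
    c = frame
    q_ew = (c[1:-1, 2:] - c[1:-1, :-2]) / ds_hv
    q_ns = (c[:-2, 1:-1] - c[2:, 1:-1]) / ds_hv
    q_ne_sw = (c[:-2, 2:] - c[2:, :-2]) / diag_ds_um
    q_nw_se = (c[:-2, :-2] - c[2:, 2:]) / diag_ds_um
    mag = np.sqrt((q_ew**2 + q_ns**2 + q_ne_sw**2 + q_nw_se**2) / 4.0)
    values = np.full(frame.shape, np.nan)
    values[1:-1, 1:-1] = mag
    return GradientMap(values=values)


def normalize_gradient(grad: GradientMap, frame: np.ndarray,
                       eps: float = LOCAL_MEAN_EPS) -> GradientMap:
    """Divide each magnitude by the mean intensity of its 3x3 neighbourhood.

    Pixels whose local mean falls below ``eps`` are flagged undefined
    (NaN) and excluded from thresholding.
    """
    frame = validate_frame(frame)
    if grad.values.shape != frame.shape:
        raise ValueError("shape mismatch between gradient map and frame")
    local_mean = ndimage.uniform_filter(frame, size=3)
    out = np.where(local_mean >= eps, grad.values / np.maximum(local_mean, eps),
                   np.nan)
    return GradientMap(values=out)


# ---------------------------------------------------------------------------
# Stage 4: blur reference and correction


def build_cov_reference(reference: ImageStack, eps: float = LOCAL_MEAN_EPS) -> CoVMap:
    """Mean-contrast reference from a non-aggregating stack.

    The per-pixel coefficient of variation (3x3 window SD over mean) is
    averaged over frames, lightly smoothed, and normalized by its maximum
    over the channel interior, so unaffected regions sit near 1 and blurred
    regions below 1.
    """
    if len(reference) == 0:
        raise ValueError("degenerate reference: empty stack")
    per_frame = np.empty(reference.frames.shape)
    for i, frame in enumerate(reference):
        m = ndimage.uniform_filter(frame, size=3)
        m2 = ndimage.uniform_filter(frame**2, size=3)
        sd = np.sqrt(np.clip(m2 - m**2, 0.0, None))
        per_frame[i] = np.where(m >= eps, sd / np.maximum(m, eps), 0.0)
    # per-pixel median over frames: robust to sporadic structure passages,
    # leaving the steady background-contrast level the blur attenuates
    cov = np.median(per_frame, axis=0)
    cov = ndimage.uniform_filter(cov, size=5)
    # erode well past the wall-edge response (PSF + window + smoothing)
    # so neither walls nor single pixels set the normalization level
    interior = ndimage.binary_erosion(reference.geometry.channel_mask(),
                                      iterations=8)
    # the median of the deep interior estimates the unaffected level far
    # more stably than the maximum, which a single contrasted pixel sets
    peak = np.median(cov[interior]) if interior.any() else cov.max()
    if peak <= 0:
        raise ValueError("degenerate reference: constant stack")
    values = np.clip(cov / peak, 1e-6, 1.0)
    # unaffected regions scatter a few percent below the normalization
    # level in finite stacks; snap them to exactly 1 so no correction leaks
    values[values >= 0.95] = 1.0
    return CoVMap(values=values)


def correct_blur(grad: GradientMap, cov: CoVMap) -> GradientMap:
    """Restore gradients in blurred regions by dividing by the CoV map.

    Applied only where the reference CoV is below 1; unaffected regions are
    untouched.  The rule is the package default; any map -> map rule can be
    substituted upstream.
    """
    if grad.values.shape != cov.values.shape:
        raise ValueError("shape mismatch between gradient and CoV maps")
    factor = np.where(cov.values < 1.0, cov.values, 1.0)
    return GradientMap(values=grad.values / factor)


# ---------------------------------------------------------------------------
# Stages 5-6: calibration, thresholding, structure extraction

_EIGHT = np.ones((3, 3), int)


def _prepare_gradient(frame: np.ndarray, config: PipelineConfig,
                      mask: np.ndarray, cov: CoVMap | None) -> np.ndarray:
    """Full pre-processing chain up to the normalized gradient map."""
    f = enhance_contrast(frame, config.contrast_percentiles, mask=mask)
    f = correct_illumination(f, mask=mask)
    g = local_gradient_magnitude(f, config.geometry, diag_ds_um=config.diag_ds_um)
    g = normalize_gradient(g, f)
    if config.blur_correction and cov is not None:
        g = correct_blur(g, cov)
    return g.values


def _threshold_areas(gvals: np.ndarray, threshold: float, interior: np.ndarray,
                     px_area: float, min_area_um2: float):
    """Label the thresholded map and return component pixel counts and slices."""
    binary = np.zeros(gvals.shape, bool)
    np.greater(gvals, threshold, out=binary, where=np.isfinite(gvals))
    binary &= interior
    labels, n = ndimage.label(binary, structure=_EIGHT)
    if n == 0:
        return labels, np.array([], int), np.array([], int)
    counts = np.bincount(labels.ravel())[1:]
    keep = np.nonzero(counts * px_area >= min_area_um2)[0] + 1
    return labels, counts, keep


def calibrate_threshold(reference: ImageStack, config: PipelineConfig,
                        rel_tol: float = 0.02, max_iter: int = 60,
                        cov: CoVMap | None = None):
    """Bisection on the threshold until the mean structure area matches Ac.

    The mean connected-structure area (after the small-component noise
    rule) decreases monotonically with the threshold; bisection brackets
    the target Ac and returns ``(threshold, achieved_mean_um2)``.
    """
    if len(reference) == 0:
        raise ValueError("calibration failed: empty reference stack")
    geom = config.geometry
    px_area = geom.um_per_px**2
    min_area = config.noise_fraction * config.Ac_um2
    mask = geom.channel_mask()
    interior = ndimage.binary_erosion(mask, iterations=2)
    gmaps = [_prepare_gradient(fr, config, mask, cov) for fr in reference]
    finite = np.concatenate([g[np.isfinite(g) & interior] for g in gmaps])
    if finite.size == 0:
        raise ValueError("calibration failed: no defined gradients")

    def mean_area(t: float) -> float:
        areas = []
        for g in gmaps:
            _, counts, keep = _threshold_areas(g, t, interior, px_area, min_area)
            if keep.size:
                areas.append(counts[keep - 1] * px_area)
        if not areas:
            return 0.0
        return float(np.mean(np.concatenate(areas)))

    lo = float(np.percentile(finite, 50.0))
    hi = float(np.percentile(finite, 99.99))
    m_lo, m_hi = mean_area(lo), mean_area(hi)
    if not (m_lo > config.Ac_um2 > m_hi):
        raise ValueError(
            "calibration failed: target mean area not bracketed "
            f"({m_lo:.2f} .. {m_hi:.2f} um^2)"
        )
    t, m = lo, m_lo
    for _ in range(max_iter):
        t = 0.5 * (lo + hi)
        m = mean_area(t)
        if abs(m - config.Ac_um2) <= rel_tol * config.Ac_um2:
            break
        if m > config.Ac_um2:
            lo = t
        else:
            hi = t
    # a usable reference puts the threshold far beyond the bulk of the
    # background gradient distribution; a threshold within a few times its
    # median means the stack contains no structures to calibrate on
    if t < 8.0 * float(np.median(finite)):
        raise ValueError("calibration failed: threshold indistinguishable "
                         "from background noise (no structures in reference)")
    return t, m


def detect_structures(stack: ImageStack, threshold: float,
                      config: PipelineConfig, cov: CoVMap | None = None) -> StructureTable:
    """Run the full chain on every frame and extract structure records.

    Per frame: preprocessing, normalized (optionally blur-corrected)
    gradient, binarization at ``threshold`` inside the channel interior,
    8-connected components, removal of components below
    ``noise_fraction * Ac``, then per-component area, normalized area A*,
    normalized centroid, branch label and border flag.
    """
    geom = stack.geometry
    px_area = geom.um_per_px**2
    min_area = config.noise_fraction * config.Ac_um2
    mask = geom.channel_mask()
    interior = ndimage.binary_erosion(mask, iterations=2)
    nr, nc = geom.frame_shape_px
    rows_out: list[dict] = []
    for fi, frame in enumerate(stack):
        g = _prepare_gradient(frame, config, mask, cov)
        labels, counts, keep = _threshold_areas(g, threshold, interior, px_area,
                                                min_area)
        if keep.size == 0:
            continue
        idx = labels.ravel()
        rr, cc = np.mgrid[0:nr, 0:nc]
        sum_r = np.bincount(idx, weights=rr.ravel())[1:]
        sum_c = np.bincount(idx, weights=cc.ravel())[1:]
        border = np.zeros(labels.shape, bool)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        border_labels = np.unique(labels[border])
        for lab in keep:
            n_px = int(counts[lab - 1])
            cr = sum_r[lab - 1] / n_px
            ccol = sum_c[lab - 1] / n_px
            xs, ys = geom.to_normalized_coords((cr, ccol))
            area = n_px * px_area
            rows_out.append(
                {
                    "frame_index": fi,
                    "pixel_count": n_px,
                    "area_um2": area,
                    "area_norm": area / config.Ac_um2,
                    "xstar": float(xs),
                    "ystar": float(ys),
                    "branch": str(geom.branch_of(xs, ys)),
                    "touches_border": bool(lab in border_labels),
                }
            )
    if rows_out:
        records = pd.DataFrame(rows_out)
    else:
        records = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            STRUCTURE_COLUMNS, [int, int, float, float, float, float, object, bool])})
    return StructureTable(records=records, Ac_um2=config.Ac_um2,
                          provenance=config.digest())
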