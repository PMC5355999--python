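"""Ground-truthed synthetic scenes and analytic bifurcating velocity fields.

The generator emulates the statistical structure the downstream analysis
assumes for brightfield microscopy of flowing red-blood-cell suspensions:

* dark cells and rouleaux-like aggregates on a bright background, rendered
  as chains of overlapping absorbing discs (Beer-Lambert attenuation with
  intracellular speckle), so aggregates form connected regions of similar
  intensity bounded by steep edges;
* aggregate projected areas drawn from a left-truncated exponential law;
* size-dependent wall margins: larger aggregates are kept farther from the
  side walls of the branch they occupy;
* Gaussian vignette illumination, optical point-spread blur, additive
  sensor noise and optional locally blurred regions;
* analytic, mass-conserving bifurcating flow at a prescribed flow ratio,
  built from a stream function so the fields are divergence-free.

Every stochastic draw flows from one generator seeded by ``rng_seed``, so
scenes are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, ndimage, optimize

from .core import ChannelGeometry, ImageStack
from .flow_split import VelocityField

# Renderer optics (chosen once to emulate transmission imaging of a dense
# suspension at cell scale; see docs/methods.md for rationale):
BACKGROUND_LEVEL = 0.88       # bright-field background before vignetting
CELL_OPTICAL_DENSITY = 4.0    # per-cell Beer-Lambert density (near-opaque interiors)
CELL_DENSITY_JITTER = 0.10    # relative per-cell density variation
CELL_TEXTURE = 0.35           # lognormal sigma of intracellular density speckle
BAND_AMPLITUDE = 0.2          # relative amplitude of the cell-stacking bands
BAND_PERIOD_UM = 2.6          # spacing of the banding along the chain axis
PSF_SIGMA_PX = 0.6            # optical point-spread sigma
GRAIN_SIGMA_PX = 1.6          # correlation length of the suspension grain
WALL_LEVEL = 0.45             # opaque region outside the channel
CHAIN_SPACING_FACTOR = 1.5    # centre spacing of neighbouring discs, in radii

# Area of the overlap lens of two equal discs of unit radius whose centres
# are CHAIN_SPACING_FACTOR apart.
_LENS_UNIT = 2.0 * math.acos(CHAIN_SPACING_FACTOR / 2.0) - (
    CHAIN_SPACING_FACTOR / 2.0
) * math.sqrt(4.0 - CHAIN_SPACING_FACTOR**2)


def default_margin_fn(astar, slope: float = 0.05):
    """Minimum normalized distance from a side wall for size A*.

    Linear in A* (slope per unit A*), capped below 0.5 so a feasible band
    always remains.
    """
    return np.minimum(slope * np.asarray(astar, float), 0.45)


@dataclass
class SceneSpec:
    """Statistical description of a synthetic image stack."""

    n_frames: int = 50
    structures_per_frame: float = 80.0
    mean_Astar: float = 2.0
    lower_trunc_Astar: float = 0.5
    Ac_um2: float = 15.0
    margin_fn: Callable = default_margin_fn
    vignette_strength: float = 0.25
    noise_sd: float = 0.012
    blur_regions: Sequence[tuple] = ()  # (row0, row1, col0, col1, sigma)
    hct_appearance: float = 0.25
    rng_seed: int = 0
    branches: tuple = ("parent", "left", "right")

    def __post_init__(self) -> None:
        if self.mean_Astar <= self.lower_trunc_Astar:
            raise ValueError("mean_Astar must exceed the lower truncation")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class FlowProfileSpec:
    """Lateral velocity profile and flow split of the bifurcating flow."""

    profile_kind: str = "parabolic"  # plug | parabolic | blunt
    mean_speed_um_s: float = 320.0
    qstar_right: float = 0.5
    blunt_exponent: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.qstar_right < 1.0):
            raise ValueError("invalid split: qstar_right must lie in (0, 1)")
        if self.mean_speed_um_s <= 0:
            raise ValueError("mean_speed must be positive")

    def profile(self, s):
        """Normalized lateral profile phi(s), s in [-0.5, 0.5], mean 1."""
        s = np.asarray(s, float)
        if self.profile_kind == "plug":
            return np.ones_like(s)
        if self.profile_kind == "parabolic":
            return 1.5 * (1.0 - 4.0 * s**2)
        if self.profile_kind == "blunt":
            m = self.blunt_exponent
            return (m + 1.0) / m * (1.0 - np.abs(2.0 * s) ** m)
        raise ValueError(f"unknown profile_kind {self.profile_kind!r}")

    def cumulative(self, s):
        """Cumulative flux fraction from the left wall, Phi(-0.5)=0, Phi(0.5)=1."""
        s = np.atleast_1d(np.asarray(s, float))
        out = np.array(
            [integrate.quad(lambda t: self.profile(t), -0.5, si)[0] for si in s]
        )
        return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# Ground truth sampling


GROUND_TRUTH_COLUMNS = [
    "frame_index",
    "n_cells",
    "true_area_um2",
    "true_Astar",
    "center_xstar",
    "center_ystar",
    "branch",
    "angle_rad",
    "radius_um",
]


@dataclass
class GroundTruth:
    """Per-structure truth for a rendered stack (one row per structure)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GROUND_TRUTH_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"ground truth missing columns {missing}")

    def __len__(self) -> int:
        return len(self.records)


def _chain_radius_um(target_area_um2: float, n_cells: int) -> float:
    """Disc radius so an n-cell straight chain's union area equals target."""
    denom = n_cells * math.pi - (n_cells - 1) * _LENS_UNIT
    return math.sqrt(target_area_um2 / denom)


def _chain_union_area(radius_um: float, n_cells: int) -> float:
    return radius_um**2 * (n_cells * math.pi - (n_cells - 1) * _LENS_UNIT)


def _branch_segments(geometry: ChannelGeometry, buffer_star: float):
    """Axial extent of each branch in normalized coords, clipped to the frame."""
    nr, nc = geometry.frame_shape_px
    x_lo, y_hi = geometry.to_normalized_coords((0.0, 0.0))
    x_hi, y_lo = geometry.to_normalized_coords((nr - 1.0, nc - 1.0))
    b = buffer_star
    return {
        "parent": (y_lo + b, -0.5),
        "left": (x_lo + b, -0.5),
        "right": (0.5, x_hi - b),
    }


def sample_ground_truth(spec: SceneSpec, geometry: ChannelGeometry) -> GroundTruth:
    """Draw structure sizes and positions for every frame of a scene.

    Sizes follow the left-truncated exponential (a shifted exponential with
    mean ``mean_Astar - lower_trunc``); lateral positions are uniform within
    the size-dependent admissible band ``|s| <= 0.5 - margin_fn(A*)``;
    axial positions are uniform along the populated branches.
    """
    if np.any(np.asarray(spec.margin_fn(np.array([1.0, 50.0]))) >= 0.5):
        raise ValueError("infeasible margin: margin_fn must stay below 0.5")
    rng = np.random.default_rng(spec.rng_seed)
    segs = _branch_segments(geometry, buffer_star=0.15)
    branches = [b for b in spec.branches if b in segs]
    lengths = np.array([segs[b][1] - segs[b][0] for b in branches], float)
    if len(branches) == 0 or np.any(lengths <= 0):
        raise ValueError("no feasible branch segments inside the frame")
    weights = lengths / lengths.sum()

    rows = []
    scale = spec.mean_Astar - spec.lower_trunc_Astar
    for fi in range(spec.n_frames):
        k = rng.poisson(spec.structures_per_frame)
        if k == 0:
            continue
        astar = spec.lower_trunc_Astar + rng.exponential(scale, size=k)
        area = astar * spec.Ac_um2
        n_cells = np.maximum(1, np.round(area / spec.Ac_um2).astype(int))
        margins = np.minimum(np.asarray(spec.margin_fn(astar), float), 0.499)
        cross = rng.uniform(-(0.5 - margins), 0.5 - margins)
        which = rng.choice(len(branches), size=k, p=weights)
        ax_lo = np.array([segs[branches[w]][0] for w in which])
        ax_hi = np.array([segs[branches[w]][1] for w in which])
        axial = rng.uniform(ax_lo, ax_hi)
        for j in range(k):
            br = branches[which[j]]
            if br == "parent":
                xs, ys = cross[j], axial[j]
                base_angle = math.pi / 2.0  # chains align with the flow axis
            else:
                xs, ys = axial[j], cross[j]
                base_angle = 0.0
            radius = _chain_radius_um(area[j], int(n_cells[j]))
            rows.append(
                {
                    "frame_index": fi,
                    "n_cells": int(n_cells[j]),
                    "true_area_um2": _chain_union_area(radius, int(n_cells[j])),
                    "true_Astar": area[j] / spec.Ac_um2,
                    "center_xstar": xs,
                    "center_ystar": ys,
                    "branch": br,
                    "angle_rad": base_angle + rng.normal(0.0, 0.2),
                    "radius_um": radius,
                }
            )
    if rows:
        records = pd.DataFrame(rows)
    else:
        records = pd.DataFrame({c: pd.Series(dtype=float) for c in GROUND_TRUTH_COLUMNS})
        records["frame_index"] = records["frame_index"].astype(int)
    return GroundTruth(records=records)


# ---------------------------------------------------------------------------
# Rendering


def _disc_coverage(dens_map: np.ndarray, row: float, col: float, radius_px: float,
                   weight: float, band: tuple | None = None) -> None:
    """Add ``weight`` times the anti-aliased coverage of a disc in place.

    ``band`` = (axis_row, axis_col, period_px, phase) applies a sinusoidal
    density modulation along the chain axis, emulating the dark/bright
    banding of stacked cells.
    """
    nr, nc = dens_map.shape
    r0 = max(0, int(math.floor(row - radius_px - 2)))
    r1 = min(nr, int(math.ceil(row + radius_px + 3)))
    c0 = max(0, int(math.floor(col - radius_px - 2)))
    c1 = min(nc, int(math.ceil(col + radius_px + 3)))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rr - row, cc - col)
    cov = np.clip(radius_px - dist + 0.5, 0.0, 1.0)
    if band is not None:
        a_r, a_c, period_px, phase = band
        s = (rr - row) * a_r + (cc - col) * a_c
        cov = cov * (1.0 + BAND_AMPLITUDE
                     * np.sin(2.0 * math.pi * s / period_px + phase))
    dens_map[r0:r1, c0:c1] += weight * cov


def render_stack(gt: GroundTruth, geometry: ChannelGeometry, spec: SceneSpec,
                 label: str = "synthetic") -> ImageStack:
    """Render a ground-truth scene into a brightfield-like image stack.

    Each structure is a chain of overlapping absorbing discs; background is
    a bright field under a Gaussian vignette; intracellular speckle gives
    aggregates internal contrast; the whole frame is blurred by the optical
    PSF before sensor noise is added.  Deterministic given ``spec.rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 0xBEEF]))
    nr, nc = geometry.frame_shape_px
    rows_g, cols_g = np.mgrid[0:nr, 0:nc]
    r0, c0 = nr / 2.0, nc / 2.0
    sigma_v = 0.45 * min(nr, nc)
    vignette = 1.0 - spec.vignette_strength * (
        1.0 - np.exp(-((rows_g - r0) ** 2 + (cols_g - c0) ** 2) / (2.0 * sigma_v**2))
    )
    background = BACKGROUND_LEVEL * (1.0 - 0.3 * spec.hct_appearance)
    channel = geometry.channel_mask()

    frames = np.empty((spec.n_frames, nr, nc))
    px = geometry.um_per_px
    by_frame = gt.records.groupby("frame_index") if len(gt) else None
    spacing = CHAIN_SPACING_FACTOR
    for fi in range(spec.n_frames):
        dens = np.zeros((nr, nc))
        if by_frame is not None and fi in by_frame.groups:
            sub = by_frame.get_group(fi)
            for rec in sub.itertuples():
                row_c, col_c = geometry.to_pixel_coords(rec.center_xstar,
                                                        rec.center_ystar)
                n = int(rec.n_cells)
                rad_px = rec.radius_um / px
                step = spacing * rad_px
                # chain centres symmetric about the structure centre;
                # angle measured from the +col axis, rows increase downward
                drow = -math.sin(rec.angle_rad) * step
                dcol = math.cos(rec.angle_rad) * step
                offsets = np.arange(n) - (n - 1) / 2.0
                band = (-math.sin(rec.angle_rad), math.cos(rec.angle_rad),
                        BAND_PERIOD_UM / px, rng.uniform(0.0, 2.0 * math.pi))
                for k, off in enumerate(offsets):
                    d = CELL_OPTICAL_DENSITY * (1.0 + CELL_DENSITY_JITTER
                                                * rng.standard_normal())
                    _disc_coverage(dens, float(row_c) + off * drow,
                                   float(col_c) + off * dcol, rad_px, d,
                                   band=band)
        # intracellular speckle: lognormal density modulation, emulating the
        # strong banding of stacked cells while keeping absorption positive
        speckle = np.exp(CELL_TEXTURE * (rng.standard_normal((nr, nc))
                                         - CELL_TEXTURE / 2.0))
        dens = dens * speckle
        img = background * vignette * np.exp(-dens)
        # unresolved-suspension granularity: a dense flowing suspension gives
        # the in-channel background a cell-scale grain (correlation ~1 px
        # at this magnification) whose strength scales with haematocrit
        granularity = 0.32 * spec.hct_appearance
        if granularity > 0:
            grain = ndimage.gaussian_filter(rng.standard_normal((nr, nc)),
                                            GRAIN_SIGMA_PX)
            # smoothing a unit white field leaves sd = 1/(2*sigma*sqrt(pi))
            grain *= granularity * (2.0 * GRAIN_SIGMA_PX * math.sqrt(math.pi))
            img = img * np.clip(1.0 + grain, 0.0, None)
        img = np.where(channel, img, WALL_LEVEL * vignette)
        img = ndimage.gaussian_filter(img, PSF_SIGMA_PX)
        if spec.noise_sd > 0:
            img = img + spec.noise_sd * rng.standard_normal((nr, nc))
        # local blur degrades the recorded contrast (applied to the noisy
        # image), which is what the CoV reference senses and corrects
        for (rr0, rr1, cc0, cc1, bsig) in spec.blur_regions:
            pad = int(math.ceil(4 * bsig))
            pr0, pr1 = max(0, rr0 - pad), min(nr, rr1 + pad)
            pc0, pc1 = max(0, cc0 - pad), min(nc, cc1 + pad)
            blurred = ndimage.gaussian_filter(img[pr0:pr1, pc0:pc1], bsig)
            img[rr0:rr1, cc0:cc1] = blurred[rr0 - pr0:rr1 - pr0, cc0 - pc0:cc1 - pc0]
        frames[fi] = np.clip(img, 0.0, 1.0)
    return ImageStack(frames=frames, geometry=geometry, label=label)


# ---------------------------------------------------------------------------
# Analytic bifurcating velocity fields


def make_velocity_field(geometry: ChannelGeometry, flow: FlowProfileSpec,
                        grid_spacing_um: float = 5.0) -> VelocityField:
    """Evaluate the analytic bifurcating flow on a rectilinear grid.

    The field derives from a stream function that blends the parent-branch
    profile into the two daughter outflow profiles across the junction
    square, so it is mass-conserving by construction: the parent carries the
    chosen lateral profile toward the junction and the right daughter takes
    the flux fraction ``qstar_right``.
    """
    W = geometry.width_um
    if grid_spacing_um > W / 10.0:
        raise ValueError("grid spacing must resolve the width (>= 10 points)")
    nr, nc = geometry.frame_shape_px
    x_lo, y_hi = geometry.to_normalized_coords((0.0, 0.0))
    x_hi, y_lo = geometry.to_normalized_coords((nr - 1.0, nc - 1.0))
    y_hi = min(y_hi, 0.5)
    xs = np.arange(x_lo * W, x_hi * W + 1e-9, grid_spacing_um)
    ys = np.arange(y_lo * W, y_hi * W + 1e-9, grid_spacing_um)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    u, v, valid = _analytic_velocity(X / W, Y / W, flow, W)
    return VelocityField(grid_x_um=xs, grid_y_um=ys, u_um_s=u, v_um_s=v, valid=valid)


def _analytic_velocity(xstar, ystar, flow: FlowProfileSpec, width_um: float):
    """Velocity (u, v) in um/s at normalized positions, plus validity mask."""
    xstar = np.asarray(xstar, float)
    ystar = np.asarray(ystar, float)
    Up = flow.mean_speed_um_s
    qR = flow.qstar_right
    qL = 1.0 - qR
    phi_x = flow.profile(np.clip(xstar, -0.5, 0.5))
    phi_y = flow.profile(np.clip(ystar, -0.5, 0.5))
    Phi_x = _cumulative_vec(flow, np.clip(xstar, -0.5, 0.5))
    Phi_y = _cumulative_vec(flow, np.clip(ystar, -0.5, 0.5))

    in_parent = (np.abs(xstar) <= 0.5) & (ystar < -0.5)
    in_junction = (np.abs(xstar) <= 0.5) & (np.abs(ystar) <= 0.5)
    in_left = (xstar < -0.5) & (np.abs(ystar) <= 0.5)
    in_right = (xstar > 0.5) & (np.abs(ystar) <= 0.5)

    u = np.zeros_like(xstar)
    v = np.zeros_like(xstar)
    v = np.where(in_parent, Up * phi_x, v)
    u = np.where(in_left, -qL * Up * phi_y, u)
    u = np.where(in_right, qR * Up * phi_y, u)
    # junction: psi = -Qp*Phi(x)*(1-Phi(y)) - qL*Qp*Phi(y);  Qp = Up*W
    u_j = Up * (Phi_x - qL) * phi_y
    v_j = Up * phi_x * (1.0 - Phi_y)
    u = np.where(in_junction, u_j, u)
    v = np.where(in_junction, v_j, v)
    valid = in_parent | in_junction | in_left | in_right
    return u, v, valid


def _cumulative_vec(flow: FlowProfileSpec, s: np.ndarray) -> np.ndarray:
    """Closed-form cumulative flux fraction (quadrature-free for speed)."""
    s = np.asarray(s, float)
    if flow.profile_kind == "plug":
        return s + 0.5
    if flow.profile_kind == "parabolic":
        return 1.5 * (s + 0.5) - 2.0 * (s**3 + 0.125)
    # blunt: integrate (m+1)/m * (1 - |2s|^m)
    m = flow.blunt_exponent
    c = (m + 1.0) / m
    prim = c * (s - np.sign(s) * np.abs(2.0 * s) ** (m + 1) / (2.0 * (m + 1.0)))
    prim0 = c * (-0.5 + 0.5 / (m + 1.0))
    return prim - prim0


def analytic_flow_split(flow: FlowProfileSpec, tol: float = 1e-6) -> float:
    """Flow-split location x*_fs from the cumulative flux of the profile.

    Root of  1 - Phi(x*) = qstar_right,  i.e. the lateral position in the
    parent branch splitting the incoming flux in the prescribed ratio.
    Serves as the independent oracle for the streamline-based locator.
    """
    target = 1.0 - flow.qstar_right
    f = lambda s: flow.cumulative(s) - target
    return float(optimize.brentq(f, -0.5, 0.5, xtol=tol))
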