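"""Velocity-field validation, flow ratio, streamlines and the flow split.

Gridded 2-D velocity fields (as exported by common PIV tools) are validated
with a normalized median test, the flow ratio Q* = U_D/U_P is computed from
mean speeds in per-branch regions of interest, and the flow-split location
x*_fs — the parent-branch coordinate of the separating streamline — is
located by bisection on streamline seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import ChannelGeometry


@dataclass
class VelocityField:
    """Velocities on a rectilinear grid.

    ``grid_x_um`` (nx,) and ``grid_y_um`` (ny,) are monotone node
    coordinates; ``u_um_s``/``v_um_s`` are (ny, nx) component arrays and
    ``valid`` flags nodes inside the measured region.
    """

    grid_x_um: np.ndarray
    grid_y_um: np.ndarray
    u_um_s: np.ndarray
    v_um_s: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid_x_um = np.asarray(self.grid_x_um, float)
        self.grid_y_um = np.asarray(self.grid_y_um, float)
        self.u_um_s = np.asarray(self.u_um_s, float)
        self.v_um_s = np.asarray(self.v_um_s, float)
        if np.any(np.diff(self.grid_x_um) <= 0) or np.any(np.diff(self.grid_y_um) <= 0):
            raise ValueError("grid coordinates must be strictly increasing")
        shape = (self.grid_y_um.size, self.grid_x_um.size)
        if self.u_um_s.shape != shape or self.v_um_s.shape != shape:
            raise ValueError("component arrays must be (ny, nx)")
        if self.valid is None:
            self.valid = np.ones(shape, bool)
        else:
            self.valid = np.asarray(self.valid, bool)
        if not np.all(np.isfinite(self.u_um_s[self.valid])) or not np.all(
            np.isfinite(self.v_um_s[self.valid])
        ):
            raise ValueError("non-finite velocity at valid node")

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u_um_s, self.v_um_s)


def write_velocity_field(field: VelocityField, path) -> None:
    """Write whitespace-delimited columns x_um y_um u_um_s v_um_s valid."""
    X, Y = np.meshgrid(field.grid_x_um, field.grid_y_um, indexing="xy")
    data = np.column_stack(
        [X.ravel(), Y.ravel(), field.u_um_s.ravel(), field.v_um_s.ravel(),
         field.valid.ravel().astype(int)]
    )
    header = "x_um y_um u_um_s v_um_s valid"
    np.savetxt(path, data, header=header, fmt="%.6g")


def read_velocity_field(path) -> VelocityField:
    """Read a field written by :func:`write_velocity_field` (or any text file
    with columns x, y, u, v and optionally a validity flag)."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 4:
        raise ValueError("expected columns x_um y_um u_um_s v_um_s [valid]")
    xs = np.unique(data[:, 0])
    ys = np.unique(data[:, 1])
    shape = (ys.size, xs.size)
    if data.shape[0] != ys.size * xs.size:
        raise ValueError("grid is not rectilinear-complete")
    ix = np.searchsorted(xs, data[:, 0])
    iy = np.searchsorted(ys, data[:, 1])
    u = np.zeros(shape)
    v = np.zeros(shape)
    valid = np.ones(shape, bool)
    u[iy, ix] = data[:, 2]
    v[iy, ix] = data[:, 3]
    if data.shape[1] >= 5:
        valid[iy, ix] = data[:, 4] > 0.5
    return VelocityField(xs, ys, u, v, valid)


# ---------------------------------------------------------------------------
# Normalized median test


def _neighbor_stack(arr: np.ndarray) -> np.ndarray:
    """(8, ny, nx) array of the 8-neighbour values, NaN outside the grid."""
    ny, nx = arr.shape
    padded = np.full((ny + 2, nx + 2), np.nan)
    padded[1:-1, 1:-1] = arr
    shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    return np.stack([padded[1 + dr:ny + 1 + dr, 1 + dc:nx + 1 + dc] for dr, dc in shifts])


def normalized_median_filter(field: VelocityField, threshold: float = 2.0,
                             eps: float = 0.1) -> VelocityField:
    """Flag and replace outlier vectors by the normalized median test.

    Per node and component: residual = |v - median(neighbours)| /
    (median(|neighbour - median|) + eps'), where eps' is ``eps`` expressed
    in units of the field's RMS speed over valid nodes.  Nodes whose
    residual exceeds ``threshold`` in either component are replaced by the
    component-wise neighbour median.
    """
    if field.grid_x_um.size < 3 or field.grid_y_um.size < 3:
        raise ValueError("grid must be at least 3x3")
    rms = float(np.sqrt(np.mean(field.speed[field.valid] ** 2))) if field.valid.any() else 1.0
    eps_abs = eps * (rms if rms > 0 else 1.0)

    u = np.where(field.valid, field.u_um_s, np.nan)
    v = np.where(field.valid, field.v_um_s, np.nan)
    flagged = np.zeros(u.shape, bool)
    med_u = med_v = None
    import warnings as _warnings
    with _warnings.catch_warnings():
        # corner nodes can have all-NaN neighbourhoods; their residual is 0
        _warnings.simplefilter("ignore", RuntimeWarning)
        for comp, store in ((u, "u"), (v, "v")):
            nb = _neighbor_stack(comp)
            med = np.nanmedian(nb, axis=0)
            resid_nb = np.nanmedian(np.abs(nb - med), axis=0)
            resid = np.abs(comp - med) / (resid_nb + eps_abs)
            flagged |= np.nan_to_num(resid, nan=0.0) > threshold
            if store == "u":
                med_u = med
            else:
                med_v = med

    new_u = field.u_um_s.copy()
    new_v = field.v_um_s.copy()
    repl = flagged & field.valid & np.isfinite(med_u) & np.isfinite(med_v)
    new_u[repl] = med_u[repl]
    new_v[repl] = med_v[repl]
    out = VelocityField(field.grid_x_um, field.grid_y_um, new_u, new_v,
                        field.valid.copy())
    out.flagged = flagged  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# Flow ratio


def compute_flow_ratio(field: VelocityField, geometry: ChannelGeometry) -> dict:
    """Flow fraction Q* = U_D/U_P for each daughter branch.

    Mean axial speeds are taken over fixed regions of interest one to two
    channel widths away from the junction in each branch; because all
    branches share one cross-section the velocity ratio equals the flow
    ratio.
    """
    W = geometry.width_um
    xs = field.grid_x_um / W
    ys = field.grid_y_um / W
    X, Y = np.meshgrid(xs, ys, indexing="xy")

    def roi_mean(mask: np.ndarray, component: np.ndarray) -> float:
        mask = mask & field.valid
        if not mask.any():
            raise ValueError("roi error: region of interest outside grid")
        return float(np.mean(np.abs(component[mask])))

    parent = (np.abs(X) <= 0.5) & (Y >= -2.0) & (Y <= -1.0)
    left = (np.abs(Y) <= 0.5) & (X >= -2.0) & (X <= -1.0)
    right = (np.abs(Y) <= 0.5) & (X >= 1.0) & (X <= 2.0)
    u_p = roi_mean(parent, field.v_um_s)
    if u_p == 0:
        raise ValueError("roi error: zero parent speed")
    return {
        "left": roi_mean(left, field.u_um_s) / u_p,
        "right": roi_mean(right, field.u_um_s) / u_p,
    }


# ---------------------------------------------------------------------------
# Streamlines


@dataclass
class Streamline:
    """Integrated trajectory in normalized coordinates."""

    points: np.ndarray  # (n, 2) of (x*, y*)
    termination: str    # left_exit | right_exit | parent_exit | boundary | max_steps

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("streamline must have at least 2 points")


class _BilinearField:
    """Fast bilinear velocity interpolation, zero outside the grid."""

    def __init__(self, field: VelocityField):
        self.xs = field.grid_x_um
        self.ys = field.grid_y_um
        self.u = np.where(field.valid, field.u_um_s, 0.0)
        self.v = np.where(field.valid, field.v_um_s, 0.0)

    def __call__(self, x: float, y: float) -> tuple[float, float]:
        xs, ys = self.xs, self.ys
        if not (xs[0] <= x <= xs[-1] and ys[0] <= y <= ys[-1]):
            return 0.0, 0.0
        i = min(np.searchsorted(xs, x) - 1, xs.size - 2)
        j = min(np.searchsorted(ys, y) - 1, ys.size - 2)
        i = max(i, 0)
        j = max(j, 0)
        tx = (x - xs[i]) / (xs[i + 1] - xs[i])
        ty = (y - ys[j]) / (ys[j + 1] - ys[j])
        w00 = (1 - tx) * (1 - ty)
        w10 = tx * (1 - ty)
        w01 = (1 - tx) * ty
        w11 = tx * ty
        u = (w00 * self.u[j, i] + w10 * self.u[j, i + 1]
             + w01 * self.u[j + 1, i] + w11 * self.u[j + 1, i + 1])
        v = (w00 * self.v[j, i] + w10 * self.v[j, i + 1]
             + w01 * self.v[j + 1, i] + w11 * self.v[j + 1, i + 1])
        return u, v


def trace_streamline(field: VelocityField, seed: tuple[float, float],
                     width_um: float = 100.0, step_um: float | None = None,
                     max_steps: int = 20000) -> Streamline:
    """Trace a streamline from a normalized seed by fixed-step RK4.

    The velocity direction field is integrated with a fixed spatial step
    (default a quarter of the grid spacing) and bilinear interpolation;
    integration stops on leaving the grid, entering a stagnant region, or
    after ``max_steps``.
    """
    interp = _BilinearField(field)
    if step_um is None:
        step_um = 0.25 * float(np.min(np.diff(field.grid_x_um)))
    x = seed[0] * width_um
    y = seed[1] * width_um
    u0, v0 = interp(x, y)
    speed_floor = 1e-9 + 1e-6 * float(np.max(field.speed))
    if math.hypot(u0, v0) < speed_floor:
        raise ValueError("stagnant seed")

    def direction(px: float, py: float):
        u, v = interp(px, py)
        s = math.hypot(u, v)
        if s < speed_floor:
            return None
        return u / s, v / s

    pts = [(x, y)]
    termination = "max_steps"
    for _ in range(max_steps):
        d1 = direction(x, y)
        if d1 is None:
            termination = "boundary"
            break
        d2 = direction(x + 0.5 * step_um * d1[0], y + 0.5 * step_um * d1[1])
        d3 = direction(x + 0.5 * step_um * (d2 or d1)[0], y + 0.5 * step_um * (d2 or d1)[1])
        d4 = direction(x + step_um * (d3 or d1)[0], y + step_um * (d3 or d1)[1])
        if d2 is None or d3 is None or d4 is None:
            # partial step toward the boundary
            x += step_um * d1[0]
            y += step_um * d1[1]
            pts.append((x, y))
            termination = "boundary"
            break
        x += step_um / 6.0 * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
        y += step_um / 6.0 * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
        pts.append((x, y))
        if x < field.grid_x_um[0]:
            termination = "left_exit"
            break
        if x > field.grid_x_um[-1]:
            termination = "right_exit"
            break
        if y < field.grid_y_um[0]:
            termination = "parent_exit"
            break
        if y > field.grid_y_um[-1]:
            termination = "boundary"
            break
    points = np.asarray(pts) / width_um
    if len(points) < 2:
        points = np.vstack([points, points[-1] + 1e-12])
    return Streamline(points=points, termination=termination)


@dataclass
class FlowSplitResult:
    """Flow fraction and separating-streamline location in the parent."""

    qstar_right: float
    xstar_fs: float
    bracket_width: float

    def __post_init__(self) -> None:
        if not (0.0 < self.qstar_right < 1.0):
            raise ValueError("qstar_right must lie in (0, 1)")
        if not (-0.5 <= self.xstar_fs <= 0.5):
            raise ValueError("xstar_fs must lie in [-0.5, 0.5]")


def _exit_side(field: VelocityField, sl: Streamline,
               width_um: float = 100.0) -> str | None:
    if sl.termination == "left_exit":
        return "left"
    if sl.termination == "right_exit":
        return "right"
    x_final, y_final = sl.points[-1]
    if x_final < -0.5:
        return "left"
    if x_final > 0.5:
        return "right"
    # stalled near the junction stagnation region: the lateral drift along
    # the trailing points tells which daughter the streamline feeds
    interp = _BilinearField(field)
    xs, ys = field.grid_x_um, field.grid_y_um
    for px, py in sl.points[::-1][:20]:
        x_um = float(np.clip(px * width_um, xs[0], xs[-1] - 1e-9))
        y_um = float(np.clip(py * width_um, ys[0], ys[-1] - 1e-9))
        u, _ = interp(x_um, y_um)
        if abs(u) > 1e-12:
            return "left" if u < 0 else "right"
    return None


def find_flow_split(field: VelocityField, geometry: ChannelGeometry,
                    tol: float = 0.005, transect_ystar: float = -2.0,
                    step_um: float | None = None) -> FlowSplitResult:
    """Locate x*_fs by bisection on streamline seeds along a parent transect.

    Streamlines seeded across the parent branch at ``transect_ystar`` are
    classified by the daughter they exit into; x*_fs is the midpoint of the
    final bracket between left- and right-exiting seeds.
    """
    W = geometry.width_um
    y0 = max(transect_ystar, field.grid_y_um[0] / W + 0.05)

    def side_of(xstar: float) -> str | None:
        sl = trace_streamline(field, (xstar, y0), width_um=W, step_um=step_um)
        return _exit_side(field, sl, width_um=W)

    margin = 0.02
    lo, hi = -0.5 + margin, 0.5 - margin
    side_lo, side_hi = side_of(lo), side_of(hi)
    if side_lo is None or side_hi is None or side_lo == side_hi:
        raise ValueError("degenerate split: all seeds exit one side")
    # convention: seeds left of the split exit left
    if side_lo != "left":
        raise ValueError("degenerate split: inverted field topology")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        side = side_of(mid)
        if side is None:
            # the seed rides the separating streamline itself
            half = 0.5 * tol
            lo, hi = mid - half, mid + half
            break
        if side == "left":
            lo = mid
        else:
            hi = mid
    qr = compute_flow_ratio(field, geometry)["right"]
    return FlowSplitResult(qstar_right=qr, xstar_fs=0.5 * (lo + hi),
                           bracket_width=hi - lo)
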