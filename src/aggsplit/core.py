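"""Shared domain types, coordinate conventions and file I/O.

The physical setting is a T-shaped microchannel bifurcation: a parent branch
(width W = 100 um, depth D = 40 um) feeds two opposing daughter branches of
the same cross-section.  All positions are expressed in normalized
coordinates x* = x/W, y* = y/W with the origin at the intersection of the
parent- and daughter-branch axes, so the parent branch width spans
x* in [-0.5, 0.5].

Image raster convention: pixel (row, col) centres define coordinates, the
x* axis increases with column (toward the right daughter) and the y* axis
increases upward (toward decreasing row).  The parent branch lies below the
junction (y* <= -0.5) and flows upward toward it; the daughter branches
occupy |y*| <= 0.5 on either side of the junction square.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("aggsplit")

#: Columns of the on-disk structure table, in order.
STRUCTURE_COLUMNS = [
    "frame_index",
    "pixel_count",
    "area_um2",
    "area_norm",
    "xstar",
    "ystar",
    "branch",
    "touches_border",
]

BRANCHES = ("parent", "left", "right", "junction")


@dataclass(frozen=True)
class ChannelGeometry:
    """Physical and pixel description of the T-junction and its frame.

    Parameters
    ----------
    width_um, depth_um : float
        Channel width W and depth D in micrometres.
    um_per_px : float
        Spatial resolution of the imaging.
    frame_shape_px : (rows, cols)
        Shape of an acquired frame.
    junction_origin_px : (row, col)
        Pixel location of the intersection of the parent- and
        daughter-branch axes (the origin of the normalized frame).
    parent_axis : str
        Direction of parent-branch flow in the image; only the default
        "up" (parent below the junction, flowing toward decreasing row)
        is currently implemented.
    """

    width_um: float = 100.0
    depth_um: float = 40.0
    um_per_px: float = 0.65
    frame_shape_px: tuple[int, int] = (700, 1216)
    junction_origin_px: tuple[float, float] = (160.0, 608.0)
    parent_axis: str = "up"

    def __post_init__(self) -> None:
        if min(self.width_um, self.depth_um, self.um_per_px) <= 0:
            raise ValueError("all lengths must be strictly positive")
        r, c = self.junction_origin_px
        nr, nc = self.frame_shape_px
        if not (0 <= r < nr and 0 <= c < nc):
            raise ValueError("junction_origin_px outside frame")
        if self.width_um / self.um_per_px > nc:
            raise ValueError("channel width exceeds frame extent")
        if self.parent_axis != "up":
            raise ValueError("only parent_axis='up' is supported")

    @property
    def width_px(self) -> float:
        return self.width_um / self.um_per_px

    def to_normalized_coords(self, point_px) -> tuple:
        """Map pixel (row, col) to normalized (x*, y*).

        Accepts scalars or arrays; the transform is an affine bijection.
        """
        row, col = np.asarray(point_px[0], float), np.asarray(point_px[1], float)
        r0, c0 = self.junction_origin_px
        xstar = (col - c0) * self.um_per_px / self.width_um
        ystar = (r0 - row) * self.um_per_px / self.width_um
        return xstar, ystar

    def to_pixel_coords(self, xstar, ystar) -> tuple:
        """Inverse of :meth:`to_normalized_coords`."""
        r0, c0 = self.junction_origin_px
        col = np.asarray(xstar, float) * self.width_um / self.um_per_px + c0
        row = r0 - np.asarray(ystar, float) * self.width_um / self.um_per_px
        return row, col

    def branch_of(self, xstar, ystar) -> np.ndarray:
        """Label normalized positions by branch.

        Rectangular masks: the junction square is |x*| <= 0.5, |y*| <= 0.5;
        the parent lies below it and the daughters to either side.
        Positions outside the channel arms fall back to the nearest label
        by the same rectangles extended (callers normally pass in-channel
        centroids only).
        """
        scalar = np.isscalar(xstar) or (np.ndim(xstar) == 0 and np.ndim(ystar) == 0)
        xstar = np.atleast_1d(np.asarray(xstar, float))
        ystar = np.atleast_1d(np.asarray(ystar, float))
        xstar, ystar = np.broadcast_arrays(xstar, ystar)
        out = np.full(xstar.shape, "junction", dtype=object)
        out[(ystar < -0.5) & (np.abs(xstar) <= 0.5)] = "parent"
        out[xstar < -0.5] = "left"
        out[xstar > 0.5] = "right"
        return out[0] if scalar else out

    def channel_mask(self) -> np.ndarray:
        """Boolean mask of the channel interior on the frame grid."""
        nr, nc = self.frame_shape_px
        rows, cols = np.mgrid[0:nr, 0:nc]
        xs, ys = self.to_normalized_coords((rows, cols))
        junction = (np.abs(xs) <= 0.5) & (np.abs(ys) <= 0.5)
        parent = (np.abs(xs) <= 0.5) & (ys < -0.5)
        daughters = np.abs(ys) <= 0.5
        return junction | parent | daughters

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_shape_px"] = list(self.frame_shape_px)
        d["junction_origin_px"] = list(self.junction_origin_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelGeometry":
        d = dict(d)
        d["frame_shape_px"] = tuple(d["frame_shape_px"])
        d["junction_origin_px"] = tuple(d["junction_origin_px"])
        return cls(**d)


def validate_frame(frame: np.ndarray) -> np.ndarray:
    """Check a frame is a finite 2-D array with values in [0, 1]."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    if frame.min() < 0 or frame.max() > 1:
        raise ValueError("frame intensities must lie in [0, 1]")
    return frame


@dataclass
class ImageStack:
    """Ordered grayscale frames sharing one geometry.

    ``frames`` is an (n, rows, cols) float array with intensities in [0, 1].
    """

    frames: np.ndarray
    geometry: ChannelGeometry
    label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __iter__(self):
        return iter(self.frames)


@dataclass
class StructureTable:
    """Detected connected structures with areas and normalized centroids.

    ``records`` is a DataFrame with :data:`STRUCTURE_COLUMNS`; ``Ac_um2``
    is the characteristic single-RBC area used to normalize areas to A*.
    """

    records: pd.DataFrame
    Ac_um2: float = 15.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.Ac_um2 <= 0:
            raise ValueError("Ac_um2 must be positive")
        missing = [c for c in STRUCTURE_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"schema error: missing columns {missing}")
        self.records = self.records[STRUCTURE_COLUMNS].reset_index(drop=True)
        if len(self.records):
            if (self.records["pixel_count"] < 1).any():
                raise ValueError("pixel_count must be >= 1")
            if not np.allclose(
                self.records["area_norm"] * self.Ac_um2,
                self.records["area_um2"],
                rtol=1e-6,
                atol=1e-9,
            ):
                raise ValueError("schema error: area_norm inconsistent with Ac_um2")

    def __len__(self) -> int:
        return len(self.records)

    def in_branch(self, branch: str) -> pd.DataFrame:
        return self.records[self.records["branch"] == branch]


@dataclass
class PipelineConfig:
    """Algorithm parameters for the detection and statistics pipeline."""

    Ac_um2: float = 15.0
    noise_fraction: float = 0.20
    truncation_lower_Astar: float = 0.5
    gradient_threshold: float | None = None  # None -> calibrate
    blur_correction: bool = False
    rng_seed: int = 0
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    # percentile anchors of the contrast stretch; the lower anchor sits at
    # the frame minimum because structure interiors occupy only a small,
    # scene-dependent fraction of the channel — any positive lower
    # percentile can clip them flat in sparse scenes
    contrast_percentiles: tuple[float, float] = (0.0, 99.8)
    diag_ds_um: float = 1.61  # printed value; geometric 2*sqrt(2)*um_per_px also valid

    def __post_init__(self) -> None:
        if not (0 < self.noise_fraction < 1):
            raise ValueError("noise_fraction must lie in (0, 1)")
        if self.truncation_lower_Astar < 0:
            raise ValueError("truncation_lower_Astar must be >= 0")

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance."""
        d = dataclasses.asdict(self)
        d["geometry"] = self.geometry.to_dict()
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["geometry"] = self.geometry.to_dict()
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        d["geometry"] = ChannelGeometry.from_dict(d["geometry"])
        if "contrast_percentiles" in d:
            d["contrast_percentiles"] = tuple(d["contrast_percentiles"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Image I/O


def _rescale_to_unit(arr: np.ndarray) -> np.ndarray:
    """Rescale integer images by their bit depth; floats are taken as-is."""
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / info.max
    return np.clip(arr.astype(float), 0.0, 1.0)


def load_image_stack(path_spec, geometry: ChannelGeometry, label: str = "") -> ImageStack:
    """Load a grayscale stack from a multipage TIFF or a directory of frames.

    Frames are ordered lexicographically by filename; 8/16-bit intensities
    are rescaled to [0, 1] by bit depth.
    """
    path = Path(path_spec)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff", ".png"}
        )
        if not files:
            raise FileNotFoundError(f"no frames found in {path}")
        arrays = []
        for f in files:
            if f.suffix.lower() == ".png":
                import imageio.v3 as iio

                arrays.append(iio.imread(f))
            else:
                arrays.append(tifffile.imread(f))
    elif path.exists():
        data = tifffile.imread(path)
        arrays = list(data) if data.ndim == 3 else [data]
    else:
        raise FileNotFoundError(f"no frames: {path}")

    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among frames: {sorted(shapes)}")
    frames = np.stack([_rescale_to_unit(a) for a in arrays])
    for fr in frames:
        validate_frame(fr)
    return ImageStack(frames=frames, geometry=geometry, label=label or path.name)


def write_image_stack(stack: ImageStack, path, bitdepth: int = 16) -> None:
    """Write a stack as a multipage TIFF at 8 or 16 bit."""
    if bitdepth == 16:
        data = np.round(np.clip(stack.frames, 0, 1) * 65535).astype(np.uint16)
    elif bitdepth == 8:
        data = np.round(np.clip(stack.frames, 0, 1) * 255).astype(np.uint8)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    tifffile.imwrite(path, data)


# ---------------------------------------------------------------------------
# Structure table I/O


def write_structure_table(table: StructureTable, path) -> None:
    """Write a structure table as CSV with a metadata header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# Ac_um2={table.Ac_um2!r} provenance={table.provenance}\n")
        table.records.to_csv(fh, index=False)


def read_structure_table(path) -> StructureTable:
    """Read a structure table written by :func:`write_structure_table`.

    Validates the area_norm * Ac == area_um2 invariant on load.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("# Ac_um2="):
            raise ValueError("schema error: missing Ac_um2 header")
        meta = header[2:].strip()
        ac_part, _, prov_part = meta.partition(" provenance=")
        Ac = float(ac_part.split("=", 1)[1])
        records = pd.read_csv(fh)
    missing = [c for c in STRUCTURE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"schema error: missing columns {missing}")
    if len(records) == 0:
        records = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            STRUCTURE_COLUMNS,
            [int, int, float, float, float, float, object, bool],
        )})
    return StructureTable(records=records, Ac_um2=Ac, provenance=prov_part)
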