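"""Core containers for DCE-MRI transport analysis.

Storage convention: images are ``(row, col)`` arrays with ``x`` = column
(increasing right) and ``y`` = row (increasing *down*).  All physics is done
in this storage frame; the flip to an anatomical "y up" frame happens once,
at the plotting/rose boundary (see :mod:`iffmap.viz`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ConcentrationStack",
    "TransportField",
    "RegionMask",
    "RoiPolygon",
    "STATUS_OK",
    "STATUS_DEGENERATE",
    "STATUS_ILL_CONDITIONED",
    "STATUS_NEGATIVE_D_CLIPPED",
    "STATUS_NEGATIVE_D_REJECTED",
    "STATUS_UNSOLVED",
]

# per-pixel solve status codes (uint8 map in TransportField.status)
STATUS_OK = 0
STATUS_DEGENERATE = 1
STATUS_ILL_CONDITIONED = 2
STATUS_NEGATIVE_D_CLIPPED = 3  # still counted as valid
STATUS_NEGATIVE_D_REJECTED = 4
STATUS_UNSOLVED = 255  # outside mask / excluded border


@dataclass
class ConcentrationStack:
    """A contrast-concentration image time series on one 2D slice.

    Parameters
    ----------
    frames
        ``(n_frames, ny, nx)`` nonnegative array; MR signal intensity is
        treated as proportional to local contrast concentration.
    frame_times
        Acquisition times in seconds from the first frame, strictly
        increasing, one per frame.
    pixel_spacing
        In-plane pixel edge length in mm (square pixels assumed).
    pre_contrast_count
        Number of leading frames acquired before contrast arrival; these
        provide the background for subtraction.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    pixel_spacing: float
    pre_contrast_count: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (t, ny, nx), got shape {self.frames.shape}")
        if self.frame_times.shape != (self.frames.shape[0],):
            raise ValueError("frame_times length must match number of frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if not 0 <= self.pre_contrast_count <= self.frames.shape[0]:
            raise ValueError("pre_contrast_count out of range")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def post_frames(self) -> np.ndarray:
        return self.frames[self.pre_contrast_count :]

    def require_minimum_frames(self) -> None:
        """Enforce the protocol minimum: >=1 pre- and >=3 post-contrast frames."""
        n_post = self.n_frames - self.pre_contrast_count
        if self.pre_contrast_count < 1:
            raise ValueError("stack needs at least one pre-contrast frame")
        if n_post < 3:
            raise ValueError(f"stack needs at least three post-contrast frames, got {n_post}")

    def copy(self) -> "ConcentrationStack":
        return ConcentrationStack(
            frames=self.frames.copy(),
            frame_times=self.frame_times.copy(),
            pixel_spacing=self.pixel_spacing,
            pre_contrast_count=self.pre_contrast_count,
        )


@dataclass
class TransportField:
    """Per-pixel transport parameters: isotropic D plus a 2D velocity field.

    Invalid pixels (degenerate or ill-conditioned solves, excluded borders,
    pixels outside the analysis mask) carry ``NaN`` in all parameter maps and
    ``False`` in ``valid_mask``; they are excluded from every summary.

    ``units`` is either ``"pixel-frame"`` (D in px^2/frame, u in px/frame,
    where one frame is the mean inter-frame interval) or ``"physical"``
    (mm^2/s and mm/s).
    """

    diffusion: np.ndarray
    velocity_x: np.ndarray
    velocity_y: np.ndarray
    valid_mask: np.ndarray
    pixel_spacing: float = 1.0
    units: str = "pixel-frame"
    frame_interval_s: float | None = None
    status: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.diffusion = np.asarray(self.diffusion, dtype=float)
        self.velocity_x = np.asarray(self.velocity_x, dtype=float)
        self.velocity_y = np.asarray(self.velocity_y, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        shapes = {
            self.diffusion.shape,
            self.velocity_x.shape,
            self.velocity_y.shape,
            self.valid_mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError("all transport maps must share one grid shape")
        if self.status is not None and self.status.shape != self.diffusion.shape:
            raise ValueError("status map must share the grid shape")
        d_valid = self.diffusion[self.valid_mask]
        if d_valid.size and (np.any(~np.isfinite(d_valid)) or np.any(d_valid < 0)):
            raise ValueError("diffusion must be finite and nonnegative at valid pixels")
        if self.units not in ("pixel-frame", "physical"):
            raise ValueError(f"unknown units tag {self.units!r}")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.diffusion.shape

    def speed(self) -> np.ndarray:
        """|u| per pixel; NaN propagated at invalid pixels."""
        return np.hypot(self.velocity_x, self.velocity_y)

    def copy(self) -> "TransportField":
        return replace(
            self,
            diffusion=self.diffusion.copy(),
            velocity_x=self.velocity_x.copy(),
            velocity_y=self.velocity_y.copy(),
            valid_mask=self.valid_mask.copy(),
            status=None if self.status is None else self.status.copy(),
        )


@dataclass
class RegionMask:
    """Boolean pixel mask for one region (tumor, parenchymal ring, ...)."""

    mask: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class RoiPolygon:
    """ROI polygon in pixel coordinates (x right, y down, 0-based centers).

    Vertices are an ordered ``(n, 2)`` array of ``(x, y)`` pairs describing a
    simple (non-self-intersecting) polygon, as drawn around a tumor on the
    image.
    """

    vertices: np.ndarray
    label: str = "tumor"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y) pairs")
        if self.vertices.shape[0] < 3:
            raise ValueError("polygon needs at least 3 vertices")

    def validate(self) -> None:
        """Raise on self-intersecting or zero-area polygons."""
        from shapely.geometry import Polygon as _ShpPolygon

        poly = _ShpPolygon(self.vertices)
        if poly.area == 0 or not poly.is_valid or not poly.is_simple:
            raise ValueError(
                f"polygon {self.label!r} is degenerate or self-intersecting "
                "(zero area or crossing edges)"
            )
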