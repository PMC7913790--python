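"""Pixel-wise inversion of the diffusion–advection equation.

For each pixel of a background-subtracted concentration stack the temporal
evolution is modelled with the explicit forward-time central-space
discretization of

    dphi/dt = D * lap(phi) - ux * dphi/dx - uy * dphi/dy,

where the advective term is the gradient expansion of div(phi u) under a
locally divergence-free assumption (the phi * div(u) part is not computable
from a single pixel's unknowns).  Each consecutive frame interval k yields
one linear equation in the three unknowns (D, ux, uy):

    (phi_{k+1} - phi_k) / dt_k = D * L(phi_k) - ux * Gx(phi_k) - uy * Gy(phi_k)

with L the 5-point Laplacian and Gx, Gy central first differences evaluated
on the earlier frame (fully explicit).  With exactly three intervals the
3x3 system is solved directly; with more, by ordinary least squares.  No
regularization is applied; quality control is by explicit status flags:

* ``degenerate`` — a flat neighbourhood (stencil coefficients below threshold)
  carries no transport information and must not become a zero-velocity
  "measurement";
* ``ill_conditioned`` — condition number above the ceiling;
* negative recovered D is clipped to zero and flagged (kept valid) by
  default, or rejected.

Internally the unknowns live in pixel–frame units (D in px^2/frame, u in
px/frame, one "frame" = the mean inter-frame interval); conversion to
mm^2/s and mm/s is a pure metadata rescale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .synthetic import gradient_stencils
from .types import (
    STATUS_DEGENERATE,
    STATUS_ILL_CONDITIONED,
    STATUS_NEGATIVE_D_CLIPPED,
    STATUS_NEGATIVE_D_REJECTED,
    STATUS_OK,
    STATUS_UNSOLVED,
    ConcentrationStack,
    RegionMask,
    TransportField,
)

__all__ = [
    "EstimationOptions",
    "PixelSystem",
    "assemble_pixel_system",
    "estimate_transport",
    "to_physical_units",
    "to_pixel_frame_units",
    "velocity_magnitude",
]


@dataclass
class EstimationOptions:
    """Tuning knobs of the per-pixel inverse solve.

    gradient_threshold_factor
        A pixel is degenerate unless every interval's stencil-coefficient
        vector norm exceeds this factor times the stack's maximum intensity.
    condition_ceiling
        Design-matrix condition number above which a pixel is flagged
        ill-conditioned instead of solved.
    negative_d_policy
        ``"clip"`` clamps a negative recovered D to 0 and flags the pixel
        (still valid); ``"reject"`` invalidates it.
    boundary_policy
        ``"exclude"`` drops the one-pixel border (no full 3x3 neighbourhood);
        one-sided stencils are deliberately not implemented.
    """

    advection_form: Literal["gradient"] = "gradient"
    gradient_threshold_factor: float = 1e-9
    condition_ceiling: float = 1e6
    negative_d_policy: Literal["clip", "reject"] = "clip"
    boundary_policy: Literal["exclude"] = "exclude"

    def __post_init__(self) -> None:
        if self.gradient_threshold_factor <= 0:
            raise ValueError("gradient threshold must be positive")
        if self.condition_ceiling <= 1:
            raise ValueError("condition ceiling must exceed 1")


@dataclass
class PixelSystem:
    """The linear system for one pixel: rows are frame intervals."""

    design: np.ndarray  # (n_intervals, 3) coefficients of (D, ux, uy)
    response: np.ndarray  # (n_intervals,) temporal differences per frame unit
    condition_number: float
    status: str  # ok | degenerate | ill_conditioned

    def solve(self) -> np.ndarray:
        """Least-squares solution (exact when square and well-conditioned)."""
        sol, *_ = np.linalg.lstsq(self.design, self.response, rcond=None)
        return sol


def _interval_scales(stack: ConcentrationStack) -> np.ndarray:
    """Per-interval durations in frame units (mean interval == 1 frame)."""
    dts = np.diff(stack.frame_times)
    return dts / dts.mean()


def _stencil_series(stack: ConcentrationStack):
    """Laplacian/gradient stencils of every frame but the last, plus responses."""
    frames = stack.frames
    taus = _interval_scales(stack)
    laps, gxs, gys = [], [], []
    for k in range(len(frames) - 1):
        lap, gx, gy = gradient_stencils(frames[k])
        laps.append(lap)
        gxs.append(gx)
        gys.append(gy)
    responses = (frames[1:] - frames[:-1]) / taus[:, None, None]
    return np.stack(laps), np.stack(gxs), np.stack(gys), responses


def _check_estimation_input(stack: ConcentrationStack) -> None:
    if stack.pre_contrast_count != 0:
        raise ValueError("estimation expects a background-subtracted stack (pre_contrast_count 0)")
    if stack.n_frames < 4:
        raise ValueError(
            f"fewer than 3 frame intervals ({stack.n_frames} frames): "
            "the 3 per-pixel unknowns (D, ux, uy) are underdetermined"
        )


def assemble_pixel_system(
    stack: ConcentrationStack,
    pixel: tuple[int, int],
    options: EstimationOptions | None = None,
) -> PixelSystem:
    """Build the per-interval linear system for one (row, col) pixel."""
    options = options or EstimationOptions()
    _check_estimation_input(stack)
    r, c = pixel
    ny, nx = stack.grid_shape
    if not (1 <= r < ny - 1 and 1 <= c < nx - 1):
        raise IndexError(
            f"pixel {pixel} lacks a full 3x3 neighbourhood (border excluded by policy)"
        )
    laps, gxs, gys, responses = _stencil_series(stack)
    design = np.stack([laps[:, r, c], -gxs[:, r, c], -gys[:, r, c]], axis=1)
    response = responses[:, r, c]

    threshold = options.gradient_threshold_factor * float(np.max(np.abs(stack.frames)))
    row_norms = np.linalg.norm(design, axis=1)
    if np.any(row_norms <= threshold):
        return PixelSystem(design, response, np.inf, "degenerate")
    s = np.linalg.svd(design, compute_uv=False)
    cond = float(s[0] / s[-1]) if s[-1] > 0 else np.inf
    status = "ok" if cond <= options.condition_ceiling else "ill_conditioned"
    return PixelSystem(design, response, cond, status)


def estimate_transport(
    stack: ConcentrationStack,
    mask: RegionMask | np.ndarray | None = None,
    options: EstimationOptions | None = None,
) -> TransportField:
    """Estimate (D, ux, uy) at every masked pixel of a subtracted stack.

    Solves each pixel's interval system by SVD-based least squares (exact for
    the square well-conditioned case).  Pixels that are degenerate,
    ill-conditioned, on the excluded border, or outside the mask are invalid
    (NaN maps, ``valid_mask`` False) with the reason in ``status``.

    The result is in pixel–frame units with ``frame_interval_s`` and
    ``pixel_spacing`` attached for later physical conversion.
    """
    options = options or EstimationOptions()
    _check_estimation_input(stack)
    ny, nx = stack.grid_shape
    if mask is None:
        mask_arr = np.ones((ny, nx), dtype=bool)
    else:
        mask_arr = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, dtype=bool)
    if mask_arr.shape != (ny, nx):
        raise ValueError("mask shape does not match the stack frames")
    if not mask_arr.any():
        raise ValueError("empty analysis mask")

    interior = np.zeros_like(mask_arr)
    interior[1:-1, 1:-1] = True
    solve_mask = mask_arr & interior

    laps, gxs, gys, responses = _stencil_series(stack)
    n_int = laps.shape[0]
    # (npix, n_int, 3) design and (npix, n_int) response for masked pixels
    A = np.stack(
        [laps[:, solve_mask], -gxs[:, solve_mask], -gys[:, solve_mask]], axis=2
    ).transpose(1, 0, 2)
    b = responses[:, solve_mask].T

    threshold = options.gradient_threshold_factor * float(np.max(np.abs(stack.frames)))
    row_norms = np.linalg.norm(A, axis=2)
    degenerate = np.any(row_norms <= threshold, axis=1)

    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(s[:, -1] > 0, s[:, 0] / s[:, -1], np.inf)
    ill = ~degenerate & (cond > options.condition_ceiling)
    ok = ~degenerate & ~ill

    sol = np.full((A.shape[0], 3), np.nan)
    if np.any(ok):
        s_ok = s[ok]
        inv_s = 1.0 / s_ok
        # x = V diag(1/s) U^T b
        utb = np.einsum("pij,pi->pj", U[ok], b[ok])
        sol[ok] = np.einsum("pji,pj->pi", Vt[ok], inv_s * utb)

    D_map = np.full((ny, nx), np.nan)
    ux_map = np.full((ny, nx), np.nan)
    uy_map = np.full((ny, nx), np.nan)
    status = np.full((ny, nx), STATUS_UNSOLVED, dtype=np.uint8)

    flat_status = np.full(A.shape[0], STATUS_OK, dtype=np.uint8)
    flat_status[degenerate] = STATUS_DEGENERATE
    flat_status[ill] = STATUS_ILL_CONDITIONED

    D_flat, ux_flat, uy_flat = sol[:, 0].copy(), sol[:, 1].copy(), sol[:, 2].copy()
    negative = ok & (D_flat < 0)
    if options.negative_d_policy == "clip":
        D_flat[negative] = 0.0
        flat_status[negative] = STATUS_NEGATIVE_D_CLIPPED
    else:
        D_flat[negative] = np.nan
        ux_flat[negative] = np.nan
        uy_flat[negative] = np.nan
        flat_status[negative] = STATUS_NEGATIVE_D_REJECTED

    valid_flat = (flat_status == STATUS_OK) | (flat_status == STATUS_NEGATIVE_D_CLIPPED)
    D_flat[~valid_flat] = np.nan
    ux_flat[~valid_flat] = np.nan
    uy_flat[~valid_flat] = np.nan

    D_map[solve_mask] = D_flat
    ux_map[solve_mask] = ux_flat
    uy_map[solve_mask] = uy_flat
    status[solve_mask] = flat_status

    valid = np.zeros((ny, nx), dtype=bool)
    valid[solve_mask] = valid_flat

    dts = np.diff(stack.frame_times)
    return TransportField(
        diffusion=D_map,
        velocity_x=ux_map,
        velocity_y=uy_map,
        valid_mask=valid,
        pixel_spacing=stack.pixel_spacing,
        units="pixel-frame",
        frame_interval_s=float(dts.mean()),
        status=status,
    )


def to_physical_units(
    field: TransportField,
    pixel_spacing_mm: float | None = None,
    frame_interval_s: float | None = None,
) -> TransportField:
    """Rescale a pixel–frame field to mm^2/s (D) and mm/s (u).

    Pure metadata-driven rescale: D by spacing^2 / interval, u by
    spacing / interval.  Exactly invertible by :func:`to_pixel_frame_units`.
    """
    if field.units == "physical":
        return field.copy()
    spacing = pixel_spacing_mm if pixel_spacing_mm is not None else field.pixel_spacing
    interval = frame_interval_s if frame_interval_s is not None else field.frame_interval_s
    if spacing is None or interval is None or spacing <= 0 or interval <= 0:
        raise ValueError("physical conversion needs positive pixel spacing and frame interval")
    out = field.copy()
    out.diffusion = field.diffusion * (spacing**2 / interval)
    out.velocity_x = field.velocity_x * (spacing / interval)
    out.velocity_y = field.velocity_y * (spacing / interval)
    out.units = "physical"
    out.pixel_spacing = spacing
    out.frame_interval_s = interval
    return out


def to_pixel_frame_units(
    field: TransportField,
    pixel_spacing_mm: float | None = None,
    frame_interval_s: float | None = None,
) -> TransportField:
    """Inverse of :func:`to_physical_units`."""
    if field.units == "pixel-frame":
        return field.copy()
    spacing = pixel_spacing_mm if pixel_spacing_mm is not None else field.pixel_spacing
    interval = frame_interval_s if frame_interval_s is not None else field.frame_interval_s
    if spacing is None or interval is None or spacing <= 0 or interval <= 0:
        raise ValueError("pixel-frame conversion needs positive pixel spacing and frame interval")
    out = field.copy()
    out.diffusion = field.diffusion / (spacing**2 / interval)
    out.velocity_x = field.velocity_x / (spacing / interval)
    out.velocity_y = field.velocity_y / (spacing / interval)
    out.units = "pixel-frame"
    return out


def velocity_magnitude(field: TransportField) -> np.ndarray:
    """|u| = sqrt(ux^2 + uy^2) per pixel; NaN at invalid pixels."""
    return field.speed()
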