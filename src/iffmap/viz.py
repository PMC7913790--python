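"""Flow-pattern graphics: heat maps, quiver/streamline overlays, rose plots.

Storage coordinates put y (row) increasing downward; figures are rendered
with ``origin="upper"`` and data-coordinate arrows, and rose-plot angles are
computed as ``atan2(-uy, ux)``, so a flow toward decreasing row index
appears "up"/anterior in every output.  That single documented flip is the
only place the y convention changes.

Streamlines are integrated at unit speed (arc-length parameterization) with
4th-order Runge–Kutta and bilinear interpolation: they depict the direction
structure of the field, while speed is conveyed separately by heat-map or
quiver coloring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .types import RegionMask, TransportField

__all__ = [
    "Streamline",
    "RoseHistogram",
    "compute_streamlines",
    "seed_grid",
    "rose_histogram",
    "render_heatmap",
    "render_quiver_streamlines",
    "render_rose",
    "rose_to_csv",
    "streamlines_to_csv",
]


@dataclass
class Streamline:
    """An integrated flow path: sub-pixel (x, y) points plus why it stopped."""

    points: np.ndarray  # (n, 2) of (x, y)
    termination: Literal["left_mask", "low_speed", "max_steps"]


@dataclass
class RoseHistogram:
    """Direction histogram of the velocity field, stratified by speed.

    ``counts[i, j]`` is the number of valid pixels whose display-frame flow
    direction falls in ``[dir_edges[i], dir_edges[i+1])`` and whose speed in
    ``[mag_edges[j], mag_edges[j+1])`` (end bins absorb out-of-range speeds).
    Zero-speed pixels go to ``static_count``, never to a direction bin, so
    ``counts.sum() + static_count`` equals the number of valid masked pixels.
    """

    counts: np.ndarray  # (n_dir_bins, n_mag_bins) pixel counts
    dir_edges: np.ndarray  # degrees, [0, 360]
    mag_edges: np.ndarray
    static_count: int
    total: int
    weighted: bool = False


# ---------------------------------------------------------------------------
# streamlines
# ---------------------------------------------------------------------------


def _bilinear(field: TransportField, x: float, y: float) -> tuple[float, float] | None:
    """Interpolate (ux, uy) at sub-pixel (x, y); None outside the valid area."""
    ny, nx = field.grid_shape
    if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
        return None
    x0 = min(int(np.floor(x)), nx - 2)
    y0 = min(int(np.floor(y)), ny - 2)
    fx, fy = x - x0, y - y0
    w = np.array([(1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy])
    cells = [(y0, x0), (y0, x0 + 1), (y0 + 1, x0), (y0 + 1, x0 + 1)]
    if not all(field.valid_mask[r, c] for r, c in cells):
        return None
    ux = sum(wi * field.velocity_x[r, c] for wi, (r, c) in zip(w, cells))
    uy = sum(wi * field.velocity_y[r, c] for wi, (r, c) in zip(w, cells))
    return float(ux), float(uy)


def _unit_direction(field: TransportField, x: float, y: float, min_speed: float):
    u = _bilinear(field, x, y)
    if u is None:
        return None, "left_mask"
    speed = float(np.hypot(*u))
    if speed < min_speed:
        return None, "low_speed"
    return (u[0] / speed, u[1] / speed), None


def compute_streamlines(
    field: TransportField,
    seed_points: Sequence[tuple[float, float]],
    step: float = 0.5,
    max_steps: int = 500,
    min_speed: float = 1e-12,
) -> list[Streamline]:
    """Integrate unit-speed streamlines from each seed through the field.

    RK4 integration of dx/ds = u(x)/|u(x)| with bilinear velocity
    interpolation; a streamline ends when it leaves the grid or the valid
    mask (``left_mask``), when local speed drops below ``min_speed``
    (``low_speed``), or at ``max_steps``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    ny, nx = field.grid_shape
    out: list[Streamline] = []
    for sx, sy in seed_points:
        if not (0 <= sx <= nx - 1 and 0 <= sy <= ny - 1):
            raise ValueError(f"seed ({sx}, {sy}) outside the grid")
        pts = [(float(sx), float(sy))]
        reason = "max_steps"
        x, y = float(sx), float(sy)
        for _ in range(max_steps):
            k1, why = _unit_direction(field, x, y, min_speed)
            if k1 is None:
                reason = why
                break
            k2, why = _unit_direction(field, x + 0.5 * step * k1[0], y + 0.5 * step * k1[1], min_speed)
            if k2 is None:
                reason = why
                break
            k3, why = _unit_direction(field, x + 0.5 * step * k2[0], y + 0.5 * step * k2[1], min_speed)
            if k3 is None:
                reason = why
                break
            k4, why = _unit_direction(field, x + step * k3[0], y + step * k3[1], min_speed)
            if k4 is None:
                reason = why
                break
            dx = (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
            dy = (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
            x, y = x + step * dx, y + step * dy
            if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
                reason = "left_mask"
                break
            pts.append((x, y))
        out.append(Streamline(points=np.asarray(pts), termination=reason))
    return out


def seed_grid(mask: RegionMask, density: int = 8) -> list[tuple[float, float]]:
    """Regular grid of streamline seeds inside a mask, every ``density`` px."""
    rows, cols = np.nonzero(mask.mask)
    if rows.size == 0:
        return []
    seeds = []
    for r in range(rows.min(), rows.max() + 1, density):
        for c in range(cols.min(), cols.max() + 1, density):
            if mask.mask[r, c]:
                seeds.append((float(c), float(r)))
    return seeds


# ---------------------------------------------------------------------------
# rose histogram
# ---------------------------------------------------------------------------


def rose_histogram(
    field: TransportField,
    mask: RegionMask | None = None,
    n_dir_bins: int = 16,
    mag_edges: Sequence[float] | None = None,
    weighted: bool = False,
) -> RoseHistogram:
    """Bin valid masked pixels by display-frame flow direction and speed.

    Directions are ``atan2(-uy, ux)`` in degrees on [0, 360) — the y axis is
    flipped once so 90 deg means anatomically "up" (toward decreasing row).
    ``mag_edges`` default to the speed quintiles of the selected pixels.
    With ``weighted=True`` the counts are summed speeds instead of pixel
    counts (conservation then holds for the unweighted totals only).
    """
    if n_dir_bins < 4:
        raise ValueError("need at least 4 direction bins")
    sel = field.valid_mask if mask is None else (field.valid_mask & mask.mask)
    ux = field.velocity_x[sel]
    uy = field.velocity_y[sel]
    speed = np.hypot(ux, uy)
    total = int(sel.sum())

    static = speed == 0
    moving_speed = speed[~static]
    if mag_edges is None:
        if moving_speed.size:
            mag_edges = np.quantile(moving_speed, np.linspace(0, 1, 6))
            mag_edges = np.unique(mag_edges)
            if len(mag_edges) < 2:
                mag_edges = np.array([0.0, max(float(moving_speed.max()), 1.0)])
        else:
            mag_edges = np.array([0.0, 1.0])
    mag_edges = np.asarray(mag_edges, dtype=float)
    if np.any(np.diff(mag_edges) <= 0):
        raise ValueError("mag_edges must be strictly increasing")
    n_mag = len(mag_edges) - 1

    angles = np.degrees(np.arctan2(-uy[~static], ux[~static])) % 360.0
    dir_edges = np.linspace(0.0, 360.0, n_dir_bins + 1)
    dir_idx = np.minimum((angles / (360.0 / n_dir_bins)).astype(int), n_dir_bins - 1)
    mag_idx = np.clip(np.searchsorted(mag_edges, moving_speed, side="right") - 1, 0, n_mag - 1)

    weights = moving_speed if weighted else None
    counts = np.zeros((n_dir_bins, n_mag), dtype=float if weighted else int)
    np.add.at(counts, (dir_idx, mag_idx), weights if weighted else 1)

    return RoseHistogram(
        counts=counts,
        dir_edges=dir_edges,
        mag_edges=mag_edges,
        static_count=int(static.sum()),
        total=total,
        weighted=weighted,
    )


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------

_FIG_DPI = 110


def _write_sidecar(out_path: Path, payload: dict) -> None:
    with open(out_path.with_suffix(out_path.suffix + ".json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def render_heatmap(
    map2d: np.ndarray,
    mask: RegionMask | None,
    background: np.ndarray | None,
    out_path: str | Path,
    *,
    cmap: str = "inferno",
    vmin: float | None = None,
    vmax: float | None = None,
    title: str = "",
) -> Path:
    """Render a parameter map over anatomy; invalid pixels are transparent.

    The applied color-scale limits are recorded in a JSON sidecar next to
    the figure.
    """
    out_path = Path(out_path)
    map2d = np.asarray(map2d, dtype=float)
    if background is not None and background.shape != map2d.shape:
        raise ValueError("background and map shapes differ")
    shown = map2d.copy()
    if mask is not None:
        shown[~mask.mask] = np.nan
    finite = shown[np.isfinite(shown)]
    lo = float(vmin) if vmin is not None else (float(finite.min()) if finite.size else 0.0)
    hi = float(vmax) if vmax is not None else (float(finite.max()) if finite.size else 1.0)

    fig, ax = plt.subplots(figsize=(5, 5), dpi=_FIG_DPI)
    if background is not None:
        ax.imshow(background, cmap="gray", origin="upper", interpolation="nearest")
    im = ax.imshow(
        np.ma.masked_invalid(shown),
        cmap=cmap,
        origin="upper",
        vmin=lo,
        vmax=hi,
        interpolation="nearest",
    )
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_axis_off()
    fig.savefig(out_path, bbox_inches="tight")
    plt.close(fig)
    _write_sidecar(out_path, {"vmin": lo, "vmax": hi, "cmap": cmap})
    return out_path


def render_quiver_streamlines(
    field: TransportField,
    background: np.ndarray | None,
    streamlines: Sequence[Streamline] | None,
    out_path: str | Path,
    *,
    decimate: int = 1,
    cmap: str = "viridis",
    title: str = "",
) -> Path:
    """Quiver plot of the velocity field with optional streamline overlay.

    The image is drawn with ``origin="upper"`` (y down in data coordinates),
    so arrows are passed storage-frame components directly and the inverted
    axis performs the single anatomical flip; an empty streamline list gives
    a quiver-only figure.
    """
    out_path = Path(out_path)
    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    ny, nx = field.grid_shape
    fig, ax = plt.subplots(figsize=(5, 5), dpi=_FIG_DPI)
    if background is not None:
        ax.imshow(background, cmap="gray", origin="upper", interpolation="nearest")
    else:
        ax.set_xlim(-0.5, nx - 0.5)
        ax.set_ylim(ny - 0.5, -0.5)
        ax.set_aspect("equal")
    rr, cc = np.mgrid[0:ny:decimate, 0:nx:decimate]
    ux = field.velocity_x[::decimate, ::decimate]
    uy = field.velocity_y[::decimate, ::decimate]
    ok = field.valid_mask[::decimate, ::decimate] & np.isfinite(ux) & np.isfinite(uy)
    speed = np.hypot(ux[ok], uy[ok])
    ax.quiver(
        cc[ok],
        rr[ok],
        ux[ok],
        uy[ok],
        speed,
        cmap=cmap,
        angles="xy",
        scale_units="xy",
    )
    for sl in streamlines or []:
        ax.plot(sl.points[:, 0], sl.points[:, 1], color="limegreen", linewidth=1.0)
    if title:
        ax.set_title(title)
    ax.set_axis_off()
    fig.savefig(out_path, bbox_inches="tight")
    plt.close(fig)
    _write_sidecar(
        out_path,
        {"decimate": decimate, "cmap": cmap, "n_streamlines": len(streamlines or [])},
    )
    return out_path


def render_rose(rose: RoseHistogram, out_path: str | Path, *, cmap: str = "viridis") -> Path:
    """Polar (wind-rose style) plot of the direction histogram, stacked by speed bin."""
    out_path = Path(out_path)
    n_dir = rose.counts.shape[0]
    theta = np.radians(0.5 * (rose.dir_edges[:-1] + rose.dir_edges[1:]))
    width = np.radians(360.0 / n_dir)
    colors = plt.get_cmap(cmap)(np.linspace(0.2, 0.95, rose.counts.shape[1]))
    fig, ax = plt.subplots(figsize=(5, 5), dpi=_FIG_DPI, subplot_kw={"projection": "polar"})
    bottom = np.zeros(n_dir)
    for j in range(rose.counts.shape[1]):
        vals = rose.counts[:, j].astype(float)
        ax.bar(theta, vals, width=width, bottom=bottom, color=colors[j],
               edgecolor="white", linewidth=0.3,
               label=f"[{rose.mag_edges[j]:.3g}, {rose.mag_edges[j + 1]:.3g})")
        bottom += vals
    ax.legend(loc="lower left", bbox_to_anchor=(1.0, 0.0), fontsize=7, title="|u|")
    fig.savefig(out_path, bbox_inches="tight")
    plt.close(fig)
    _write_sidecar(out_path, {"static_count": rose.static_count, "total": rose.total})
    return out_path


def rose_to_csv(rose: RoseHistogram, path: str | Path) -> Path:
    """Write per-(direction, speed) bin counts as tidy CSV."""
    path = Path(path)
    lines = ["dir_lo_deg,dir_hi_deg,mag_lo,mag_hi,count"]
    for i in range(rose.counts.shape[0]):
        for j in range(rose.counts.shape[1]):
            lines.append(
                f"{rose.dir_edges[i]:.6g},{rose.dir_edges[i + 1]:.6g},"
                f"{rose.mag_edges[j]:.6g},{rose.mag_edges[j + 1]:.6g},{rose.counts[i, j]}"
            )
    lines.append(f"static,,,,{rose.static_count}")
    path.write_text("\n".join(lines) + "\n")
    return path


def streamlines_to_csv(streamlines: Sequence[Streamline], path: str | Path) -> Path:
    """Write streamline vertices as tidy CSV: streamline,point,x,y,termination."""
    path = Path(path)
    lines = ["streamline,point,x,y,termination"]
    for i, sl in enumerate(streamlines):
        for k, (x, y) in enumerate(sl.points):
            lines.append(f"{i},{k},{x:.6f},{y:.6f},{sl.termination}")
    path.write_text("\n".join(lines) + "\n")
    return path
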