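"""Loading DCE-MRI time series and building region masks.

Supported stack sources:

* a DICOM series directory (one file per frame; timing from AcquisitionTime,
  then ContentTime, then TriggerTime — tried in that documented order),
* a NIfTI-1 file laid out (x, y, t) with a JSON sidecar carrying frame times,
* a ``.npz`` array file with the same JSON sidecar.

Timing metadata is mandatory: a source that cannot state when each frame was
acquired raises instead of silently assuming a frame interval.

Coordinate convention: pixel centers sit at integer (x, y) with x = column
(right) and y = row (down); see :mod:`iffmap.types`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .types import ConcentrationStack, RegionMask, RoiPolygon

__all__ = [
    "load_stack",
    "save_stack_npz",
    "save_stack_nifti",
    "save_stack_dicom",
    "select_spanning_frames",
    "subtract_background",
    "rasterize_polygon",
    "make_parenchyma_ring",
    "load_roi_json",
    "save_roi_json",
    "mask_to_png",
    "mask_to_rle_csv",
]

log = logging.getLogger(__name__)

_SIDECAR_SUFFIX = ".json"


def _round_half_up(x):
    """Deterministic scalar/array rounding with .5 always rounding up."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


# ---------------------------------------------------------------------------
# stack readers / writers
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".npz"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    else:
        name = path.stem
    return path.with_name(name + _SIDECAR_SUFFIX)


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing timing sidecar {sidecar}: frame times are required, not defaulted"
        )
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("frame_times", "pixel_spacing_mm"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} lacks required key {key!r}")
    return meta


def _write_sidecar(path: Path, stack: ConcentrationStack) -> None:
    meta = {
        "frame_times": [float(t) for t in stack.frame_times],
        "pixel_spacing_mm": float(stack.pixel_spacing),
        "pre_contrast_count": int(stack.pre_contrast_count),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def save_stack_npz(stack: ConcentrationStack, path: str | Path) -> Path:
    """Write frames as a compressed array with a JSON timing sidecar."""
    path = Path(path)
    np.savez_compressed(path, frames=stack.frames)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    _write_sidecar(path, stack)
    return path


def save_stack_nifti(stack: ConcentrationStack, path: str | Path) -> Path:
    """Write the stack as NIfTI-1 (x, y, t) plus a JSON timing sidecar."""
    import nibabel as nib

    path = Path(path)
    # storage (t, row, col) -> NIfTI (x=col, y=row, t)
    data = np.transpose(stack.frames, (2, 1, 0))
    affine = np.diag([stack.pixel_spacing, stack.pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float64), affine), str(path))
    _write_sidecar(path, stack)
    return path


def save_stack_dicom(stack: ConcentrationStack, directory: str | Path) -> Path:
    """Write one secondary-capture DICOM file per frame (test fixtures, QA).

    Float intensities are stored as uint16 with RescaleSlope/Intercept, so a
    round trip is exact only to that quantization. Frame times go into
    AcquisitionTime as seconds past midnight.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=["iffmap-series"])
    lo = float(stack.frames.min())
    hi = float(stack.frames.max())
    slope = (hi - lo) / 65535.0 if hi > lo else 1.0

    for i, (frame, t) in enumerate(zip(stack.frames, stack.frame_times)):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[f"iffmap-{i}"])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.InstanceNumber = i + 1
        ds.PixelSpacing = [f"{stack.pixel_spacing:.8g}", f"{stack.pixel_spacing:.8g}"]
        secs = float(t)
        hh, rem = divmod(secs, 3600)
        mm, ss = divmod(rem, 60)
        ds.AcquisitionTime = f"{int(hh):02d}{int(mm):02d}{ss:09.6f}"
        ds.Rows, ds.Columns = frame.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = f"{slope:.10g}"
        ds.RescaleIntercept = f"{lo:.10g}"
        quantized = np.round((frame - lo) / slope).astype(np.uint16)
        ds.PixelData = quantized.tobytes()
        ds.save_as(directory / f"frame_{i:04d}.dcm", enforce_file_format=True)
    return directory


def _parse_dicom_time(value: str) -> float:
    """HHMMSS.FFFFFF -> seconds past midnight."""
    value = str(value)
    hh = int(value[0:2])
    mm = int(value[2:4])
    ss = float(value[4:]) if len(value) > 4 else 0.0
    return hh * 3600 + mm * 60 + ss


def _load_dicom_series(directory: Path) -> ConcentrationStack:
    import pydicom

    files = sorted(directory.glob("*.dcm")) or sorted(
        p for p in directory.iterdir() if p.is_file()
    )
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    frames, times, spacings = [], [], []
    for f in files:
        ds = pydicom.dcmread(f)
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        frames.append(arr * slope + intercept)
        t = None
        for tag in ("AcquisitionTime", "ContentTime"):
            if getattr(ds, tag, None):
                t = _parse_dicom_time(getattr(ds, tag))
                log.debug("frame %s: time from %s", f.name, tag)
                break
        if t is None and getattr(ds, "TriggerTime", None) is not None:
            t = float(ds.TriggerTime) / 1000.0  # TriggerTime is in ms
            log.debug("frame %s: time from TriggerTime", f.name)
        if t is None:
            raise ValueError(f"{f}: no usable acquisition-time tag (refusing to guess timing)")
        times.append(t)
        if getattr(ds, "PixelSpacing", None):
            spacings.append(float(ds.PixelSpacing[0]))
    if not spacings:
        raise ValueError(f"{directory}: DICOM series lacks PixelSpacing")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes in series: {sorted(shapes)}")
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, dtype=float)[order]
    times = times - times[0]
    frames = np.stack([frames[i] for i in order])
    if np.any(np.diff(times) <= 0):
        raise ValueError("acquisition times are not strictly increasing after sorting")
    return ConcentrationStack(
        frames=frames,
        frame_times=times,
        pixel_spacing=spacings[0],
        pre_contrast_count=0,
    )


def load_stack(
    source: str | Path,
    *,
    slice_index: int | None = None,
    time_indices: Sequence[int] | None = None,
    pre_contrast_count: int | None = None,
) -> ConcentrationStack:
    """Load a DCE time series from DICOM / NIfTI / npz into a stack.

    Frames are returned sorted by acquisition time with ``frame_times`` in
    seconds from the first loaded frame.  ``time_indices`` (applied after
    time-sorting) selects a subset of frames; ``slice_index`` selects one z
    slice from 4D NIfTI input.  ``pre_contrast_count`` overrides (or, for
    DICOM, supplies) the number of leading pre-contrast frames.
    """
    source = Path(source)
    if source.is_dir():
        stack = _load_dicom_series(source)
    elif source.suffix == ".npz":
        meta = _read_sidecar(source)
        with np.load(source) as data:
            frames = data["frames"]
        stack = ConcentrationStack(
            frames=frames,
            frame_times=np.asarray(meta["frame_times"], dtype=float),
            pixel_spacing=float(meta["pixel_spacing_mm"]),
            pre_contrast_count=int(meta.get("pre_contrast_count", 0)),
        )
    elif source.suffix in (".nii", ".gz") or source.name.endswith(".nii.gz"):
        import nibabel as nib

        meta = _read_sidecar(source)
        img = nib.load(str(source))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 4:
            if slice_index is None:
                raise ValueError("4D NIfTI input requires slice_index")
            data = data[:, :, slice_index, :]
        if data.ndim != 3:
            raise ValueError(f"expected (x, y, t) NIfTI data, got shape {data.shape}")
        frames = np.transpose(data, (2, 1, 0))  # -> (t, row, col)
        stack = ConcentrationStack(
            frames=frames,
            frame_times=np.asarray(meta["frame_times"], dtype=float),
            pixel_spacing=float(meta["pixel_spacing_mm"]),
            pre_contrast_count=int(meta.get("pre_contrast_count", 0)),
        )
    else:
        raise ValueError(f"unrecognized stack source {source}")

    if pre_contrast_count is not None:
        stack.pre_contrast_count = int(pre_contrast_count)

    if time_indices is not None:
        time_indices = list(time_indices)
        if max(time_indices) >= stack.n_frames or min(time_indices) < 0:
            raise IndexError("time_indices out of range")
        n_pre = sum(1 for i in time_indices if i < stack.pre_contrast_count)
        stack = ConcentrationStack(
            frames=stack.frames[time_indices],
            frame_times=stack.frame_times[time_indices],
            pixel_spacing=stack.pixel_spacing,
            pre_contrast_count=n_pre,
        )
    if stack.n_frames < 4:
        raise ValueError(f"need at least 4 frames for analysis, got {stack.n_frames}")
    return stack


# ---------------------------------------------------------------------------
# frame selection & background subtraction
# ---------------------------------------------------------------------------


def select_spanning_frames(
    n_available: int, n_select: int = 5, pre_contrast_count: int = 1
) -> list[int]:
    """Pick analysis frames spanning a long dynamic acquisition.

    Returns the first pre-contrast frame plus ``n_select - 1`` post-contrast
    frames evenly spanning the post-contrast index range (first and last post
    frame included; intermediate positions rounded half-up).  This stands in
    for the unrecorded manual choice of a handful of frames out of a
    ~1200-frame dynamic series.
    """
    if n_select < 4:
        raise ValueError("need at least 4 analysis frames")
    if n_select > n_available:
        raise ValueError(f"cannot select {n_select} of {n_available} frames")
    if pre_contrast_count < 1:
        raise ValueError("need at least one pre-contrast frame to select")
    n_post_needed = n_select - 1
    first_post = pre_contrast_count
    last = n_available - 1
    if last - first_post + 1 < n_post_needed:
        raise ValueError("not enough post-contrast frames to span")
    post = _round_half_up(np.linspace(first_post, last, n_post_needed))
    indices = [0] + list(dict.fromkeys(int(i) for i in post))
    if len(indices) != n_select:  # rounding collisions only when nearly exhaustive
        raise ValueError("frame selection produced duplicate indices")
    return indices


def subtract_background(stack: ConcentrationStack) -> ConcentrationStack:
    """Remove the pre-contrast baseline from every post-contrast frame.

    The mean of all pre-contrast frames is subtracted pixel-wise from each
    post-contrast frame and negatives are clamped to zero (a concentration
    cannot be negative).  The returned stack holds the post frames only, with
    ``pre_contrast_count == 0``.
    """
    if stack.pre_contrast_count < 1:
        raise ValueError("background subtraction requires at least one pre-contrast frame")
    background = stack.frames[: stack.pre_contrast_count].mean(axis=0)
    post = stack.frames[stack.pre_contrast_count :] - background
    np.clip(post, 0.0, None, out=post)
    return ConcentrationStack(
        frames=post,
        frame_times=stack.frame_times[stack.pre_contrast_count :].copy(),
        pixel_spacing=stack.pixel_spacing,
        pre_contrast_count=0,
    )


# ---------------------------------------------------------------------------
# ROI polygons and masks
# ---------------------------------------------------------------------------


def rasterize_polygon(polygon: RoiPolygon, grid_shape: tuple[int, int]) -> RegionMask:
    """Rasterize a simple polygon: a pixel is in iff its center is inside.

    Inside-ness is the even-odd (crossing-number) rule.  The tie-break for a
    center exactly on the boundary is half-open: for each non-horizontal edge
    the y-interval ``[min(y), max(y))`` is half-open and only crossings
    strictly to the right of the center count, so shared edges between
    adjacent polygons claim each boundary center exactly once.
    """
    polygon.validate()
    ny, nx = grid_shape
    verts = polygon.vertices
    xs = np.arange(nx, dtype=float)
    ys = np.arange(ny, dtype=float)
    xc, yc = np.meshgrid(xs, ys)
    crossings = np.zeros(grid_shape, dtype=int)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edges never cross a scanline
        straddles = (y1 <= yc) != (y2 <= yc)
        with np.errstate(invalid="ignore"):
            xint = x1 + (yc - y1) * (x2 - x1) / (y2 - y1)
        crossings += straddles & (xc < xint)
    mask = crossings % 2 == 1
    return RegionMask(mask, label=polygon.label)


def make_parenchyma_ring(
    tumor: RegionMask, width_mm: float, pixel_spacing: float
) -> RegionMask:
    """Annulus of surrounding parenchyma built by dilating the tumor mask.

    The tumor mask is dilated with a Euclidean disk of radius
    ``round(width_mm / pixel_spacing)`` pixels (half-up) and the tumor is
    subtracted, leaving a ring clipped to the grid and disjoint from the
    tumor.
    """
    if width_mm <= 0:
        raise ValueError("ring width must be positive")
    radius = int(_round_half_up(width_mm / pixel_spacing))
    if radius < 1:
        raise ValueError(
            f"ring width {width_mm} mm rounds to a zero-pixel dilation at "
            f"{pixel_spacing} mm/px"
        )
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    structure = xx**2 + yy**2 <= radius**2
    dilated = ndimage.binary_dilation(tumor.mask, structure=structure)
    ring = dilated & ~tumor.mask
    return RegionMask(ring, label="parenchyma")


def load_roi_json(path: str | Path) -> RoiPolygon:
    """Read a polygon from JSON ``{"label": ..., "vertices": [[x, y], ...]}``."""
    with open(path) as fh:
        payload = json.load(fh)
    return RoiPolygon(vertices=np.asarray(payload["vertices"], dtype=float),
                      label=payload.get("label", "custom"))


def save_roi_json(polygon: RoiPolygon, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(
            {"label": polygon.label, "vertices": [[float(x), float(y)] for x, y in polygon.vertices]},
            fh,
            indent=1,
        )
    return path


def mask_to_png(mask: RegionMask, path: str | Path) -> Path:
    """Export a mask as an 8-bit PNG (0 outside, 255 inside)."""
    from matplotlib.image import imsave

    path = Path(path)
    imsave(path, mask.mask.astype(np.uint8) * 255, cmap="gray", vmin=0, vmax=255)
    return path


def mask_to_rle_csv(mask: RegionMask, path: str | Path) -> Path:
    """Export a mask as row-wise run-length CSV: row,start_col,length."""
    path = Path(path)
    lines = ["row,start_col,length"]
    for r, row in enumerate(mask.mask):
        padded = np.concatenate([[0], row.astype(int), [0]])
        edges = np.flatnonzero(np.diff(padded))
        for start, stop in zip(edges[::2], edges[1::2]):
            lines.append(f"{r},{start},{stop - start}")
    Path(path).write_text("\n".join(lines) + "\n")
    return path
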