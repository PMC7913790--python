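"""End-to-end orchestration: config-driven slice runs and cohort reports.

``run_slice`` executes load (or phantom simulation) -> frame selection ->
background subtraction -> transport estimation -> region summaries ->
visualization, writing every artifact plus a manifest JSON with SHA-256
hashes and the resolved configuration.  Runs are deterministic: one global
seed is expanded into independent per-stage substreams, and no output embeds
a timestamp, so identical config + seed reproduces byte-identical CSV/JSON.

``run_cohort`` aggregates many slice runs into per-patient values and runs
the cohort statistics: paired tumor vs. parenchyma comparison, Pearson
correlations of flow with age / weight / survival, two-group tests for sex /
MGMT / EGFR, and the paired pre/post-resection contrast when both stages are
present.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import image_io, summaries as summ, synthetic, viz
from .estimation import EstimationOptions, estimate_transport, velocity_magnitude
from .types import (
    STATUS_DEGENERATE,
    STATUS_NEGATIVE_D_CLIPPED,
    ConcentrationStack,
    RegionMask,
    TransportField,
)

__all__ = ["RunConfig", "run_slice", "run_cohort", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One slice analysis: either a phantom recipe or a real-data source."""

    patient_id: str = "phantom"
    slice_id: str = "0"
    resection_stage: str = "pre"
    outdir: str = "iffmap_out"
    seed: int = 0
    # exactly one input mode
    phantom: synthetic.PhantomSpec | None = None
    source: str | None = None
    slice_index: int | None = None
    # frame handling
    n_select: int = 5
    frame_times: Sequence[float] | None = None  # phantom mode sampling times
    noise_sigma: float = 0.0
    scheme: str = "gradient"
    # ROI
    roi_path: str | None = None
    ring_width_mm: float = 4.0
    parenchyma_roi_path: str | None = None
    # estimation / viz
    estimation: EstimationOptions = dc_field(default_factory=EstimationOptions)
    physical_units: bool = False
    n_dir_bins: int = 16
    streamline_step: float = 0.5
    streamline_max_steps: int = 200
    seed_density: int = 8

    def validate(self) -> None:
        if (self.phantom is None) == (self.source is None):
            raise ValueError("config must set exactly one input mode: phantom or source")
        if self.source is not None and not Path(self.source).exists():
            raise ValueError(f"input source {self.source} does not exist")
        if self.source is not None and self.roi_path is None:
            raise ValueError("real-data mode requires an ROI polygon path")
        if self.roi_path is not None and not Path(self.roi_path).exists():
            raise ValueError(f"ROI path {self.roi_path} does not exist")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML; the ``phantom`` block maps to PhantomSpec."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "phantom" in raw and raw["phantom"] is not None:
        ph = dict(raw["phantom"])
        if "grid_shape" in ph:
            ph["grid_shape"] = tuple(ph["grid_shape"])
        if "velocity" in ph:
            ph["velocity"] = tuple(ph["velocity"])
        if "blobs" in ph and ph["blobs"] is not None:
            ph["blobs"] = [tuple(b) for b in ph["blobs"]]
        raw["phantom"] = synthetic.PhantomSpec(**ph)
    if "estimation" in raw and raw["estimation"] is not None:
        raw["estimation"] = EstimationOptions(**raw["estimation"])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _resolved_config(config: RunConfig) -> dict:
    def encode(obj: Any):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    return encode(config)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _phantom_stack(config: RunConfig) -> tuple[ConcentrationStack, RegionMask, RegionMask]:
    spec = dataclasses.replace(config.phantom, seed=config.seed)
    field, initial = synthetic.make_phantom(spec)
    times = config.frame_times
    if times is None:
        times = [0.0] + [float(t) for t in range(1, config.n_select)]
    stack = synthetic.simulate_stack(
        field,
        initial,
        times,
        pre_contrast_count=1,
        noise_sigma=config.noise_sigma,
        seed=config.seed,
        scheme=config.scheme,
        dt_micro=(1.0 if config.scheme == "gradient" else None),
    )
    if spec.kind == "tumor_ring":
        tumor, ring = synthetic.phantom_region_masks(spec)
    else:
        ny, nx = spec.grid_shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        r = np.hypot(xx - (nx - 1) / 2, yy - (ny - 1) / 2)
        tumor = RegionMask(r <= min(ny, nx) / 4.0, label="tumor")
        ring_mask = image_io.make_parenchyma_ring(
            tumor, config.ring_width_mm, spec.pixel_spacing
        )
        ring = ring_mask
    return stack, tumor, ring


def _real_stack(config: RunConfig) -> tuple[ConcentrationStack, RegionMask, RegionMask]:
    stack = image_io.load_stack(config.source, slice_index=config.slice_index)
    if stack.pre_contrast_count >= 1 and stack.n_frames > config.n_select:
        idx = image_io.select_spanning_frames(
            stack.n_frames, config.n_select, stack.pre_contrast_count
        )
        stack = image_io.load_stack(
            config.source, slice_index=config.slice_index, time_indices=idx
        )
    polygon = image_io.load_roi_json(config.roi_path)
    tumor = image_io.rasterize_polygon(polygon, stack.grid_shape)
    tumor.label = "tumor"
    if config.parenchyma_roi_path:
        ppoly = image_io.load_roi_json(config.parenchyma_roi_path)
        ring = image_io.rasterize_polygon(ppoly, stack.grid_shape)
        ring.label = "parenchyma"
    else:
        ring = image_io.make_parenchyma_ring(tumor, config.ring_width_mm, stack.pixel_spacing)
    return stack, tumor, ring


def run_slice(config: RunConfig) -> dict:
    """Run the full single-slice pipeline; returns the manifest dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    stage = "load"
    artifacts: dict[str, Path] = {}
    try:
        if config.phantom is not None:
            stack, tumor, ring = _phantom_stack(config)
        else:
            stack, tumor, ring = _real_stack(config)
        artifacts["stack_npz"] = image_io.save_stack_npz(stack, outdir / "stack.npz")

        stage = "background_subtraction"
        stack.require_minimum_frames()
        subtracted = image_io.subtract_background(stack)

        stage = "estimation"
        analysis_mask = RegionMask(tumor.mask | ring.mask, label="analysis")
        field = estimate_transport(subtracted, analysis_mask, config.estimation)
        if config.physical_units:
            from .estimation import to_physical_units

            field = to_physical_units(field)
        status = field.status
        n_masked = int(analysis_mask.mask.sum())
        n_degenerate = int(((status == STATUS_DEGENERATE) & analysis_mask.mask).sum())
        n_clipped = int(((status == STATUS_NEGATIVE_D_CLIPPED) & analysis_mask.mask).sum())
        if n_degenerate:
            log.warning(
                "patient %s slice %s: %d/%d masked pixels degenerate",
                config.patient_id, config.slice_id, n_degenerate, n_masked,
            )
        if n_clipped:
            log.warning(
                "patient %s slice %s: %d pixels had negative D clipped to 0",
                config.patient_id, config.slice_id, n_clipped,
            )
        maps_path = outdir / "transport_maps.npz"
        np.savez_compressed(
            maps_path,
            diffusion=field.diffusion,
            velocity_x=field.velocity_x,
            velocity_y=field.velocity_y,
            speed=velocity_magnitude(field),
            valid_mask=field.valid_mask,
            status=field.status,
        )
        artifacts["transport_maps"] = maps_path

        stage = "summaries"
        rows = []
        for mask in (tumor, ring):
            rs = summ.summarize_region(
                field, mask, patient_id=config.patient_id,
                slice_id=config.slice_id, region=mask.label,
            )
            rows.append(rs.to_dict())
        region_csv = outdir / "region_summaries.csv"
        pd.DataFrame(rows).to_csv(region_csv, index=False, float_format="%.10g")
        artifacts["region_summaries"] = region_csv

        stage = "visualization"
        speed_map = velocity_magnitude(field)
        artifacts["heatmap_speed"] = viz.render_heatmap(
            speed_map, analysis_mask, stack.frames[-1], outdir / "speed_heatmap.png",
            title="|u| heat map",
        )
        artifacts["heatmap_diffusion"] = viz.render_heatmap(
            field.diffusion, analysis_mask, stack.frames[-1], outdir / "diffusion_heatmap.png",
            title="D heat map",
        )
        seeds = viz.seed_grid(RegionMask(analysis_mask.mask & field.valid_mask),
                              density=config.seed_density)
        lines = viz.compute_streamlines(
            field, seeds, step=config.streamline_step, max_steps=config.streamline_max_steps
        )
        artifacts["quiver_streamlines"] = viz.render_quiver_streamlines(
            field, stack.frames[-1], lines, outdir / "quiver_streamlines.png", decimate=2
        )
        rose = viz.rose_histogram(field, analysis_mask, n_dir_bins=config.n_dir_bins)
        artifacts["rose_png"] = viz.render_rose(rose, outdir / "rose.png")
        artifacts["rose_csv"] = viz.rose_to_csv(rose, outdir / "rose_counts.csv")
        artifacts["streamlines_csv"] = viz.streamlines_to_csv(lines, outdir / "streamlines.csv")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed for patient {config.patient_id} "
            f"slice {config.slice_id}: {exc}"
        ) from exc

    elapsed = time.perf_counter() - t0
    log.info(
        "patient %s slice %s done in %.2fs (%d artifacts)",
        config.patient_id, config.slice_id, elapsed, len(artifacts),
    )
    manifest = {
        "patient_id": config.patient_id,
        "slice_id": config.slice_id,
        "resection_stage": config.resection_stage,
        "config": _resolved_config(config),
        "outputs": {
            name: {"path": str(p.name), "sha256": _sha256(Path(p))}
            for name, p in sorted(artifacts.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _correlation_entry(x, y, name: str, report: dict, reasons: list[str]) -> None:
    try:
        res = summ.correlate(x, y)
        report[name] = {"test": "pearson", "r": res.r, "p": res.p, "n": res.n}
    except ValueError as exc:
        reasons.append(f"{name}: {exc}")


def run_cohort(
    configs: Sequence[RunConfig],
    clinical_csv: str | Path | pd.DataFrame,
    outdir: str | Path,
) -> dict:
    """Run every slice config, aggregate per patient, and report cohort stats.

    Patients missing a stage or covariate are excluded from the affected
    analysis only, with the reason recorded in the report's ``skipped`` list.
    Returns the report dict (also written to ``cohort_report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    slice_rows: list[summ.RegionSummary] = []
    manifests = []
    for config in configs:
        manifest = run_slice(config)
        manifests.append(manifest)
        df = pd.read_csv(Path(config.outdir) / "region_summaries.csv")
        for _, row in df.iterrows():
            slice_rows.append(
                summ.RegionSummary(
                    patient_id=str(row["patient_id"]),
                    slice_id=str(row["slice_id"]),
                    region=row["region"],
                    mean_speed=row["mean_speed"],
                    median_speed=row["median_speed"],
                    mean_diffusion=row["mean_diffusion"],
                    median_diffusion=row["median_diffusion"],
                    valid_pixel_count=int(row["valid_pixel_count"]),
                    units=row["units"],
                )
            )

    stage_of = {(c.patient_id, c.slice_id): c.resection_stage for c in configs}
    patients: list[summ.PatientSummary] = []
    keyed: dict[tuple[str, str, str], list[summ.RegionSummary]] = {}
    for rs in slice_rows:
        stage = stage_of.get((rs.patient_id, rs.slice_id), "pre")
        keyed.setdefault((rs.patient_id, rs.region, stage), []).append(rs)
    for (pid, region, stage), group in sorted(keyed.items()):
        patients.append(summ.aggregate_patient(group, resection_stage=stage))

    patient_df = pd.DataFrame([p.to_dict() for p in patients])
    patient_df.to_csv(outdir / "patient_summaries.csv", index=False, float_format="%.10g")
    cohort = summ.build_cohort_table(patient_df, clinical_csv)
    cohort.to_csv(outdir / "cohort_table.csv", index=False, float_format="%.10g")

    report: dict[str, Any] = {"n_patients": int(patient_df["patient_id"].nunique())}
    skipped: list[str] = []

    pre = cohort[cohort["resection_stage"] == "pre"] if "resection_stage" in cohort else cohort
    tumor = pre[pre["region"] == "tumor"].set_index("patient_id")
    paren = pre[pre["region"] == "parenchyma"].set_index("patient_id")
    shared = tumor.index.intersection(paren.index)

    if len(shared) >= 3:
        paired = summ.compare_regions_paired(
            tumor.loc[shared, "mean_speed"], paren.loc[shared, "mean_speed"]
        )
        report["tumor_vs_parenchyma_speed"] = {
            "t": paired.t_statistic, "t_p": paired.t_p,
            "wilcoxon": paired.wilcoxon_statistic, "wilcoxon_p": paired.wilcoxon_p,
            "headline_p": paired.headline_p, "n": paired.n, "primary": paired.primary,
        }
        paired_d = summ.compare_regions_paired(
            tumor.loc[shared, "mean_diffusion"], paren.loc[shared, "mean_diffusion"]
        )
        report["tumor_vs_parenchyma_diffusion"] = {
            "t": paired_d.t_statistic, "t_p": paired_d.t_p,
            "wilcoxon": paired_d.wilcoxon_statistic, "wilcoxon_p": paired_d.wilcoxon_p,
            "headline_p": paired_d.headline_p, "n": paired_d.n, "primary": paired_d.primary,
        }
        _correlation_entry(
            tumor.loc[shared, "mean_speed"], paren.loc[shared, "mean_speed"],
            "tumor_parenchyma_speed_correlation", report, skipped,
        )
        _correlation_entry(
            tumor.loc[shared, "mean_diffusion"], paren.loc[shared, "mean_diffusion"],
            "tumor_parenchyma_diffusion_correlation", report, skipped,
        )
    else:
        skipped.append(f"tumor vs parenchyma: only {len(shared)} patients with both regions")

    if len(tumor) >= 3:
        for covariate, name in (
            ("age_years", "velocity_vs_age"),
            ("weight_kg", "velocity_vs_weight"),
            ("survival_days", "velocity_vs_survival"),
        ):
            if covariate in tumor.columns:
                _correlation_entry(
                    tumor["mean_speed"], tumor[covariate], name, report, skipped
                )
            else:
                skipped.append(f"{name}: covariate {covariate} absent")
        if "survival_days" in tumor.columns:
            _correlation_entry(
                tumor["mean_diffusion"], tumor["survival_days"],
                "diffusion_vs_survival", report, skipped,
            )
        if {"age_years", "survival_days"} <= set(tumor.columns):
            _correlation_entry(
                tumor["age_years"], tumor["survival_days"],
                "age_vs_survival", report, skipped,
            )
    else:
        skipped.append(f"correlations: only {len(tumor)} patients (need >= 3)")

    for col, name in (("sex", "sex"), ("mgmt_status", "mgmt"), ("egfr_amplified", "egfr")):
        if col in tumor.columns and tumor[col].notna().any():
            groups = tumor.dropna(subset=[col]).groupby(col)["mean_speed"]
            levels = list(groups.groups)
            if len(levels) == 2:
                a, b = (groups.get_group(lv) for lv in levels)
                try:
                    g = summ.compare_groups(a, b)
                    report[f"speed_by_{name}"] = {
                        "groups": [str(lv) for lv in levels],
                        "welch_t": g.welch_statistic, "welch_p": g.welch_p,
                        "mannwhitney_u": g.mannwhitney_statistic,
                        "mannwhitney_p": g.mannwhitney_p,
                        "n": [g.n_a, g.n_b],
                    }
                except ValueError as exc:
                    skipped.append(f"speed_by_{name}: {exc}")
            else:
                skipped.append(f"speed_by_{name}: need exactly 2 groups, got {len(levels)}")

    if "resection_stage" in cohort.columns:
        t_all = cohort[cohort["region"] == "tumor"]
        pre_t = t_all[t_all["resection_stage"] == "pre"].set_index("patient_id")
        post_t = t_all[t_all["resection_stage"] == "post"].set_index("patient_id")
        both = pre_t.index.intersection(post_t.index)
        if len(both) >= 3:
            paired = summ.compare_regions_paired(
                pre_t.loc[both, "mean_speed"], post_t.loc[both, "mean_speed"]
            )
            report["pre_vs_post_resection_speed"] = {
                "t": paired.t_statistic, "t_p": paired.t_p,
                "wilcoxon": paired.wilcoxon_statistic, "wilcoxon_p": paired.wilcoxon_p,
                "headline_p": paired.headline_p, "n": paired.n, "primary": paired.primary,
            }
            _correlation_entry(
                pre_t.loc[both, "mean_speed"], post_t.loc[both, "mean_speed"],
                "pre_post_speed_correlation", report, skipped,
            )
        elif len(post_t):
            skipped.append(
                f"pre/post resection: only {len(both)} patients with both stages"
            )

    p_entries = [(k, v["p"]) for k, v in report.items()
                 if isinstance(v, dict) and "r" in v and "p" in v]
    if p_entries:
        adjusted = summ.benjamini_hochberg([p for _, p in p_entries])
        report["bh_adjusted_correlation_p"] = {
            k: float(q) for (k, _), q in zip(p_entries, adjusted)
        }

    report["skipped"] = skipped
    for reason in skipped:
        log.info("cohort analysis skipped: %s", reason)
    with open(outdir / "cohort_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
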