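"""Region, slice, patient and cohort summaries of transport maps.

Aggregation follows the clinical workflow: per-slice region statistics
(mean/median of |u| and D over valid pixels), an unweighted average over the
analyzed slices per patient, then cohort-level statistics — paired tumor vs.
parenchyma comparisons, Pearson correlations of flow with clinical
covariates, unpaired group tests, and paired pre/post-resection contrasts.

Small-cohort caution is built in: paired comparisons report both the paired
t-test and the Wilcoxon signed-rank test (Wilcoxon is the default headline
for n <= 14); unpaired comparisons report Welch's t with Mann–Whitney as the
alternative.  Correlation p-values are per-test (no correction), with a
Benjamini–Hochberg adjusted column emitted as supplementary output.
"""

from __future__ import annotations

import logging
from pathlib import Path
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import velocity_magnitude
from .types import RegionMask, TransportField

__all__ = [
    "RegionSummary",
    "PatientSummary",
    "CorrelationResult",
    "PairedComparisonResult",
    "GroupComparisonResult",
    "summarize_region",
    "aggregate_patient",
    "correlate",
    "compare_regions_paired",
    "compare_groups",
    "build_cohort_table",
    "benjamini_hochberg",
]

log = logging.getLogger(__name__)


@dataclass
class RegionSummary:
    """Mean/median transport statistics for one region of one slice."""

    patient_id: str
    slice_id: str
    region: str
    mean_speed: float
    median_speed: float
    mean_diffusion: float
    median_diffusion: float
    valid_pixel_count: int
    units: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PatientSummary:
    """Per-patient aggregate: unweighted mean over slice statistics."""

    patient_id: str
    region: str
    mean_speed: float  # mean over slices of slice mean |u|
    median_speed: float  # mean over slices of slice median |u|
    mean_diffusion: float
    median_diffusion: float
    n_slices: int
    units: str
    resection_stage: str = "pre"
    speed_range_fraction: float = 0.0  # (max - min) / mean of slice means, diagnostic

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str = "pearson"


@dataclass
class PairedComparisonResult:
    t_statistic: float
    t_p: float
    wilcoxon_statistic: float | None
    wilcoxon_p: float | None
    n: int
    primary: str
    note: str = ""

    @property
    def headline_p(self) -> float:
        if self.primary == "wilcoxon" and self.wilcoxon_p is not None:
            return self.wilcoxon_p
        return self.t_p


@dataclass
class GroupComparisonResult:
    welch_statistic: float
    welch_p: float
    mannwhitney_statistic: float
    mannwhitney_p: float
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# region / patient aggregation
# ---------------------------------------------------------------------------


def summarize_region(
    field: TransportField,
    mask: RegionMask,
    *,
    patient_id: str = "",
    slice_id: str = "",
    region: str | None = None,
) -> RegionSummary:
    """Mean and median |u| and D over the valid pixels of one region."""
    if mask.grid_shape != field.grid_shape:
        raise ValueError("mask and field shapes differ")
    label = region if region is not None else mask.label
    sel = mask.mask & field.valid_mask
    count = int(sel.sum())
    if count == 0:
        raise ValueError(f"region {label!r} has no valid pixels to summarize")
    speed = velocity_magnitude(field)[sel]
    diffusion = field.diffusion[sel]
    return RegionSummary(
        patient_id=patient_id,
        slice_id=slice_id,
        region=label,
        mean_speed=float(speed.mean()),
        median_speed=float(np.median(speed)),
        mean_diffusion=float(diffusion.mean()),
        median_diffusion=float(np.median(diffusion)),
        valid_pixel_count=count,
        units=field.units,
    )


def aggregate_patient(
    summaries: Sequence[RegionSummary], resection_stage: str = "pre"
) -> PatientSummary:
    """Unweighted mean over slices of each slice statistic for one region.

    Also records the spread of slice mean speeds ((max - min) / mean) as a
    diagnostic of inter-slice variability.
    """
    if not summaries:
        raise ValueError("no slice summaries to aggregate")
    patient_ids = {s.patient_id for s in summaries}
    regions = {s.region for s in summaries}
    units = {s.units for s in summaries}
    if len(patient_ids) != 1:
        raise ValueError(f"mixed patient ids {sorted(patient_ids)}")
    if len(regions) != 1:
        raise ValueError(f"mixed regions {sorted(regions)}")
    if len(units) != 1:
        raise ValueError(f"mixed units {sorted(units)}")
    # fixed evaluation order makes the aggregate exactly slice-order invariant
    summaries = sorted(summaries, key=lambda s: s.slice_id)
    mean_speeds = np.array([s.mean_speed for s in summaries])
    overall = mean_speeds.mean()
    spread = float((mean_speeds.max() - mean_speeds.min()) / overall) if overall else 0.0
    return PatientSummary(
        patient_id=summaries[0].patient_id,
        region=summaries[0].region,
        mean_speed=float(overall),
        median_speed=float(np.mean([s.median_speed for s in summaries])),
        mean_diffusion=float(np.mean([s.mean_diffusion for s in summaries])),
        median_diffusion=float(np.mean([s.median_diffusion for s in summaries])),
        n_slices=len(summaries),
        units=summaries[0].units,
        resection_stage=resection_stage,
        speed_range_fraction=spread,
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def _paired_finite(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson (default) or Spearman correlation with a two-sided p-value.

    Pairs with missing values are dropped and the effective n reported.  The
    Pearson p comes from the t transform ``t = r sqrt(n-2) / sqrt(1-r^2)``
    with n-2 degrees of freedom.
    """
    x, y = _paired_finite(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"correlation needs at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: one variable has zero variance")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n, method=method)


def compare_regions_paired(a, b, primary: str = "wilcoxon") -> PairedComparisonResult:
    """Paired comparison of two per-patient series (e.g. tumor vs parenchyma).

    Reports both the paired t-test and the Wilcoxon signed-rank test; the
    configured primary test supplies the headline p.  Degenerate difference
    patterns are handled explicitly: all-zero differences give t = 0, p = 1
    with Wilcoxon undefined; constant nonzero differences give an infinite t
    with p = 0.
    """
    a, b = _paired_finite(a, b)
    n = len(a)
    if n < 3:
        raise ValueError(f"paired comparison needs at least 3 complete pairs, got {n}")
    diff = a - b
    note = ""
    if np.all(diff == 0):
        t_stat, t_p = 0.0, 1.0
        w_stat = w_p = None
        note = "all paired differences are zero; Wilcoxon undefined"
    elif np.ptp(diff) == 0:
        t_stat = np.inf if diff[0] > 0 else -np.inf
        t_p = 0.0
        w_res = stats.wilcoxon(diff)
        w_stat, w_p = float(w_res.statistic), float(w_res.pvalue)
        note = "constant nonzero differences: t is infinite"
    else:
        t_res = stats.ttest_rel(a, b)
        t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)
        try:
            w_res = stats.wilcoxon(diff)
            w_stat, w_p = float(w_res.statistic), float(w_res.pvalue)
        except ValueError as exc:  # e.g. all differences zero after zero-handling
            w_stat = w_p = None
            note = f"Wilcoxon undefined: {exc}"
    return PairedComparisonResult(
        t_statistic=t_stat,
        t_p=t_p,
        wilcoxon_statistic=w_stat,
        wilcoxon_p=w_p,
        n=n,
        primary=primary,
        note=note,
    )


def compare_groups(values_a, values_b) -> GroupComparisonResult:
    """Unpaired two-group comparison: Welch's t with Mann–Whitney U alongside."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    welch = stats.ttest_ind(a, b, equal_var=False)
    mw = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparisonResult(
        welch_statistic=float(welch.statistic),
        welch_p=float(welch.pvalue),
        mannwhitney_statistic=float(mw.statistic),
        mannwhitney_p=float(mw.pvalue),
        n_a=len(a),
        n_b=len(b),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (supplementary output; headline stats are per-test)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adjusted, 0, 1)
    return out


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "weight_kg",
    "survival_days",
    "mgmt_status",
    "egfr_amplified",
    "resection_stage",
]


def build_cohort_table(
    patient_summaries: Sequence[PatientSummary] | pd.DataFrame,
    clinical: str | pd.DataFrame,
) -> pd.DataFrame:
    """Left-join per-patient flow aggregates to clinical covariates.

    ``clinical`` is a CSV path or DataFrame with a ``patient_id`` column (and
    optionally the other documented covariate columns).  Patients without a
    clinical row are retained with null covariates and logged; duplicate
    clinical patient ids are an error.
    """
    if isinstance(patient_summaries, pd.DataFrame):
        summary_df = patient_summaries.copy()
    else:
        summary_df = pd.DataFrame([s.to_dict() for s in patient_summaries])
    if "patient_id" not in summary_df.columns:
        raise ValueError("patient summaries lack a patient_id column")

    clinical_df = pd.read_csv(clinical) if isinstance(clinical, (str, Path)) else clinical.copy()
    if "patient_id" not in clinical_df.columns:
        raise ValueError("clinical table lacks a patient_id column")
    if clinical_df["patient_id"].duplicated().any():
        dupes = clinical_df.loc[clinical_df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids in clinical table: {dupes}")

    merged = summary_df.merge(clinical_df, on="patient_id", how="left", suffixes=("", "_clin"))
    clinical_cols = [c for c in clinical_df.columns if c != "patient_id"]
    unmatched = merged[merged[clinical_cols].isna().all(axis=1)]["patient_id"].unique()
    if len(unmatched):
        log.warning("no clinical covariates for patients: %s", ", ".join(map(str, unmatched)))
    return merged
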