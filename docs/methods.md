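# Methods

## Transport model

Contrast concentration φ(**x**, t) on a single axial 2D slice is modelled by
the diffusion–advection equation

∂φ/∂t = ∇·(D ∇φ) − ∇·(φ **u**),

with isotropic diffusion coefficient D(**x**) ≥ 0 and in-plane velocity
**u**(**x**) = (uₓ, u_y). Two modelling assumptions are made throughout:

1. **Signal proportionality.** T1-weighted signal intensity is taken as
   proportional to gadolinium concentration, so background-subtracted image
   intensities stand in for φ directly (the proportionality constant cancels
   from the linear inverse).
2. **Stationarity over the analysis window.** D and **u** are constant over
   the few frames analyzed; one map of each is produced per image stack.
   Through-plane (z) velocity is not modelled: the output is the in-plane
   component of a 3D flow and should be read as such.

Coordinates: storage arrays are (row, col) with x = column (right) and
y = row (down). Every physics computation uses this frame; the single flip
to an anatomical "y up" convention happens in the visualization layer
(plot axes inverted, rose angles computed as atan2(−u_y, uₓ)).

## Inverse problem

With the forward-time central-space (FTCS) discretization on the earlier
frame of each interval, frame pair k contributes per pixel

(φₖ₊₁ − φₖ)/Δtₖ = D·Lφₖ − uₓ·Gₓφₖ − u_y·G_yφₖ,

L the 5-point Laplacian, Gₓ/G_y central differences (pixel units, h = 1).
The advective term is the expansion ∇·(φ**u**) = **u**·∇φ + φ∇·**u** with
the φ∇·**u** part dropped: with independent per-pixel unknowns the local
divergence is not computable, so the estimator assumes locally
divergence-free flow. A coupled all-pixel formulation with a divergence
penalty is a possible extension, not implemented.

Each pixel with a full 3×3 neighbourhood and n ≥ 3 intervals yields an
n×3 system in (D, uₓ, u_y), solved by SVD least squares (exact for the
well-conditioned 3×3 case). No regularization is used; quality control is
by explicit status flags:

- **degenerate** — some interval's stencil-coefficient vector norm is below
  10⁻⁹ × max|φ| (a flat neighbourhood carries no information; flat
  background must never appear as a zero-velocity "measurement");
- **ill-conditioned** — design-matrix condition number above 10⁶;
- **negative D** — clipped to 0 and flagged by default (pixel stays valid so
  region summaries keep their spatial coverage, with an audit trail), or
  rejected under the `reject` policy. Whether a hard D ≥ 0 constraint is
  preferable is an open modelling question; both policies are exposed.

Invalid pixels carry NaN in all maps and are excluded from every summary.
The one-pixel image border has no full stencil and is always excluded.

### Units

Rows are scaled by each interval's own Δtₖ expressed in units of the mean
frame interval, so estimates come out in **pixel–frame units** (D in
px²/frame, u in px/frame, 1 frame ≡ the mean interval). Physical conversion
is a pure metadata rescale — D by spacing²/interval (mm²/s), u by
spacing/interval (mm/s) — and is exactly invertible; because the per-row Δtₖ
handling happens inside the estimator, the conversion is exact for
non-uniform frame timing too. |u| commutes with the rescale.

### Minimum stack

Background subtraction removes the mean of the pre-contrast frames from each
post-contrast frame (clamped at 0: φ is a concentration) and drops the pre
frames. Three unknowns need three intervals, i.e. **four post-subtraction
frames**; the default spanning selection therefore picks 1 pre + 4 post
frames (first pre, then post frames evenly spanning the post range, ends
included, intermediate indices rounded half-up). A stack of 1 pre + 3 post
supports background subtraction but leaves the pixel systems
underdetermined, and the estimator refuses it explicitly.

## Forward simulator

Two explicit schemes, both with an internal micro-timestep kept at a
configurable fraction (default 0.25) of the stability bound
min(h²/4D_max, h/2|u|_max); violating a user-supplied step is an error that
names the limiting constraint.

- **Conservative (default):** finite-volume flux form, zero-flux (Neumann)
  boundaries, arithmetic face averages (optional upwinding). Without a
  source it conserves the grid total to rounding error (< 10⁻⁸ relative per
  frame by a wide margin). Used for physically realistic phantoms. Note the
  discrete second moment grows at exactly 2D per unit time for this stencil
  (discrete summation by parts), which is why the heat-kernel variance check
  passes to ~10⁻¹⁴ rather than merely 1%.
- **Gradient (matched FTCS):** one update
  φ ← φ + Δt(D·Lφ − uₓ·Gₓφ − u_y·G_yφ) per micro-step. With one step per
  frame interval the forward model is *exactly* the model the inverse
  assumes, so noiseless recovery is exact to solver rounding (~10⁻¹⁰) — the
  pipeline's central self-consistency check, including for spatially varying
  piecewise fields.

The enhancement **source** is an additive per-pixel rate active on a
configurable [t_on, t_off) window, standing in for vascular gadolinium
entry; default phantoms instead use a nonzero initial blob and no source,
because background subtraction removes the baseline but not influx, and the
uptake-vs-plateau regime of a 2–3 minute acquisition is not known a priori.
Both regimes are exposed rather than asserting one.

**Noise** is additive Gaussian by default, with an optional Rician mode
(magnitude of a complex Gaussian) for low-SNR realism; frames are clamped
nonnegative as magnitude images are.

### Phantoms

`uniform` (constant D, **u**), `gaussian_blob` (constant D with a
Gaussian-windowed velocity jet), and `tumor_ring` — a central disk with one
(D, |u|) regime and an annulus with another, flow pointing radially outward,
emulating pressure-driven efflux from a tumor core. Initial conditions are
sums of Gaussian blobs. The default test pattern uses four blobs of
different widths and centers: a single Gaussian has a ring where its
Laplacian vanishes (r = σ√2), which starves D of signal along that ring;
overlapping blobs keep both gradient and Laplacian information spread over
the region of interest.

### Synthetic cohort

Per-patient (velocity, age, survival) are drawn from a trivariate Gaussian
with target correlations (defaults +0.6 velocity–survival, −0.6
velocity–age, −0.6 age–survival; the matrix is checked for positive
semi-definiteness), then shifted/scaled to marginals of 0.5 ± 0.15 (velocity,
arbitrary speed units), 60 ± 10 y (age) and 400 ± 150 d (survival), with
uncorrelated weight, sex, MGMT and EGFR covariates. At n = 1000 the sample
correlations land within ±0.05 of the targets; at n = 14 all three signs
are reproduced in ≈98% of seeds.

## Regions and statistics

The tumor ROI is a polygon rasterized by the even-odd rule at pixel centers
with a half-open boundary convention (for each non-horizontal edge the
y-interval [min(y), max(y)) is half-open and only crossings strictly right
of the center count), so adjacent polygons sharing an edge claim each
boundary pixel exactly once. The parenchymal region is either a second
polygon or (scripted default) a ring: dilation of the tumor mask by a
Euclidean disk of radius round(width/pixel spacing), minus the tumor.

Slice summaries are means/medians of |u| and D over valid masked pixels
("mean velocity magnitude" = mean of per-pixel magnitudes, not the magnitude
of the mean vector). Patient values are unweighted means over slices (slice
order fixed by sorting, making the aggregate exactly permutation-invariant);
the (max−min)/mean spread of slice means is reported as an inter-slice
variability diagnostic. Cohort statistics report Pearson r with the
two-sided p from t = r√(n−2)/√(1−r²) (Spearman available), and paired
comparisons report both the paired t-test and the Wilcoxon signed-rank test
with Wilcoxon as the default headline — at n ≤ 14 the exact signed-rank
test is the safer primary, and its discreteness makes the realized type-I
rate ≈3.5–5% at nominal 5%. Unpaired two-group comparisons use Welch's t
with Mann–Whitney alongside. Correlation p-values are reported per test; a
Benjamini–Hochberg-adjusted panel is emitted as supplementary output.
Degenerate difference patterns are handled explicitly (all-zero differences:
t = 0, p = 1, Wilcoxon undefined; constant nonzero differences: |t| = ∞,
p = 0).

## Visualization

Streamlines integrate dx/ds = **u**/|**u**| (arc length, so they show
direction structure independent of speed) with RK4 and bilinear velocity
interpolation, terminating on leaving the valid mask, speed below a floor,
or a step cap; on a rigid-rotation field a full revolution holds its radius
to ~10⁻¹⁰ relative at step 0.01·r. Speed is conveyed separately by heat
maps and quiver color. Rose histograms bin valid pixels by display-frame
direction (16 bins by default) and speed (quintile edges by default, or
fixed edges); |u| = 0 pixels go to a dedicated static count so bin totals
conserve the valid-pixel count exactly. A magnitude-weighted variant is
available; the count-based rose is the default.

## Accuracy under realistic conditions

Numbers below are what the test suite and `scripts/acceptance.py` measure
on the synthetic study conditions; they are the honest limits of the
per-pixel FTCS inversion, not defects of the implementation.

- **Noise.** At 1% Gaussian noise (of peak enhancement), 64×64, uniform
  truth D = 0.2 px²/frame, |u| = 0.447 px/frame, four-blob enhancement,
  ROI radius 16, and 1 pre + 16 post frames, the median-of-pixels estimates
  over 100 seeds are biased by ≈ +6.5% (D) and ≈ +3% (|u|). Two opposing
  mechanisms are at work: the response noise −nₖ is correlated with the
  stencil L(nₖ) of the same frame (center coefficient −4), inflating D by
  ≈ 4σ²/⟨L²⟩, while errors-in-variables attenuation pulls it down — which
  is also why the *bias* of D is not monotone in σ even though the
  per-pixel median absolute error of both D and |u| grows strictly with σ.
  With the minimal 4-frame stack (exactly determined 3×3 systems, no
  least-squares averaging) the per-row response SNR is ~2 and biases reach
  tens to hundreds of percent: pixel-wise flow maps from minimal stacks
  should be treated as qualitative.
- **Scheme mismatch.** Inverting data generated with a fine micro-step
  (i.e. real dynamics rather than the matched one-step model) misattributes
  second-order temporal terms to D, an additive error ≈ u²Δt/2. At
  D = 0.08, |u| = 0.18 px/frame (CFL numbers 0.08 and 0.18) the recovered
  median D is within 15% and |u| within 5%; for D ≪ u²Δt/2 the relative D
  error is unbounded even though |u| stays accurate. Velocity is the robust
  output of this method; D is trustworthy only where diffusion is not
  dominated by advection at the frame scale.

## What the synthetic data does and does not show

The generator reproduces the features the estimator depends on — PDE-driven
contrast dynamics with known (D, **u**), baseline frames, additive
Gaussian/Rician noise, region structure, and a cohort correlation pattern —
so passing tests demonstrate correct inversion, calibrated statistics and
deterministic plumbing. It does not emulate motion, coil inhomogeneity,
nonlinear signal–concentration response at high gadolinium concentration,
vascular input heterogeneity, partial-volume effects, or 3D through-plane
flow; accuracy on real DCE-MRI is bounded by those effects and is not
established by this test suite.

## Problem sizes and reproducibility

Test and acceptance runs use 48–128 px grids, 100-seed noise ensembles and
200-seed calibration ensembles — sizes at which every quantity above is
stable to the third significant figure across seeds. All randomness flows
from explicit seeds (`numpy.random.default_rng`; the pipeline expands one
global seed into per-stage substreams), outputs embed no timestamps, and two
runs of one config + seed produce byte-identical artifacts, verified by
SHA-256 in the run manifest.
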