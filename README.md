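# iffmap

Interstitial fluid flow (IFF) and diffusion mapping from dynamic
contrast-enhanced MRI (DCE-MRI) time series.

Bulk interstitial flow through and around a brain tumor shapes how drugs,
tracer and even invading cells move through tissue, yet it is rarely
quantified in patients. `iffmap` estimates it from a standard DCE-MRI
acquisition: treating the T1-weighted signal as proportional to the local
gadolinium concentration φ(**x**, t), each pixel's time course is modelled
with the diffusion–advection equation

∂φ/∂t = ∇·(D ∇φ) − ∇·(φ **u**)

with isotropic diffusion coefficient D(**x**) and in-plane interstitial
velocity **u**(**x**) = (uₓ, u_y), held constant over the short analysis
window. Discretizing with the forward-time central-space (FTCS) scheme, each
consecutive frame pair contributes one linear equation per pixel

(φₖ₊₁ − φₖ)/Δtₖ = D·Lφₖ − uₓ·Gₓφₖ − u_y·G_yφₖ,

where L is the 5-point Laplacian and Gₓ, G_y central first differences. With
at least three intervals the per-pixel system determines (D, uₓ, u_y) by a
direct or least-squares solve; flat or ill-conditioned pixels are flagged
invalid rather than reported as zero flow.

Around that inverse sit the pieces a full analysis needs:

- `iffmap.synthetic` — forward simulator (conservative flux form with
  zero-flux boundaries, plus a matched-discretization FTCS mode for exact
  recovery tests), phantoms with known transport fields, and a synthetic
  patient-cohort generator with a built-in velocity–age–survival correlation
  structure.
- `iffmap.image_io` — DICOM series / NIfTI / array-file loading with
  mandatory timing metadata, spanning-frame selection from long dynamic
  series, pre-contrast background subtraction, polygon-ROI rasterization and
  the dilated parenchymal-ring mask.
- `iffmap.estimation` — the pixel-wise inverse solver, status flags, and
  pixel–frame ↔ physical unit conversion.
- `iffmap.summaries` — region/slice/patient aggregation and cohort
  statistics (paired tumor vs. parenchyma tests, Pearson correlations with
  clinical covariates, two-group tests, pre/post-resection contrasts).
- `iffmap.viz` — velocity heat maps, quiver + streamline overlays (RK4,
  arc-length parameterization), and wind-rose direction histograms.
- `iffmap.pipeline` / the `iffmap` CLI — config-driven end-to-end runs with
  hashed artifact manifests and deterministic seeding.

## Worked example

Simulate a "tumor ring" phantom — a slow-flow disk (|u| = 0.05 px/frame,
D = 0.1 px²/frame) inside a faster annulus (|u| = 0.15, D = 0.2) with
radially outward flow — then run the full inverse and summarize each region:

```python
from iffmap import (
    PhantomSpec, make_phantom, phantom_region_masks, simulate_stack,
    subtract_background, estimate_transport, summarize_region,
)

spec = PhantomSpec(
    grid_shape=(64, 64), kind="tumor_ring",
    inner_speed=0.05, outer_speed=0.15,
    inner_diffusion=0.1, outer_diffusion=0.2,
    blobs=[(26.0, 26.0, 6.0, 1.0), (40.0, 38.0, 5.0, 0.8)],
)
truth, initial = make_phantom(spec)
stack = simulate_stack(truth, initial, [0, 1, 2, 3, 4], pre_contrast_count=1,
                       scheme="gradient", dt_micro=1.0)
field = estimate_transport(subtract_background(stack))
for mask in phantom_region_masks(spec):
    rs = summarize_region(field, mask)
    print(f"{rs.region:11s} mean |u| = {rs.mean_speed:.4f} px/frame   "
          f"mean D = {rs.mean_diffusion:.4f} px^2/frame   ({rs.valid_pixel_count} px)")
```

prints

```
tumor       mean |u| = 0.0500 px/frame   mean D = 0.1000 px^2/frame   (313 px)
parenchyma  mean |u| = 0.1500 px/frame   mean D = 0.2000 px^2/frame   (937 px)
```

i.e. the estimator recovers both regimes of the known field exactly (the
stack was generated at matched discretization and without noise; see
`docs/methods.md` for what noise and scheme mismatch do to accuracy). The
same pipeline is available from the shell:

```bash
iffmap estimate --config examples/ring.yaml --seed 1 --outdir out/
```

writing transport maps, region CSVs, heat map / quiver / streamline / rose
figures and a hashed manifest to `out/`.

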