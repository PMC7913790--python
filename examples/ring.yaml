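# Tumor-ring phantom: slow-flow disk inside a faster parenchymal annulus.
patient_id: RING
slice_id: s0
outdir: out
seed: 1
phantom:
  grid_shape: [64, 64]
  kind: tumor_ring
  inner_radius: 10.0
  outer_radius: 18.0
  inner_speed: 0.05
  outer_speed: 0.15
  inner_diffusion: 0.1
  outer_diffusion: 0.2
  blobs:
    - [26.0, 26.0, 6.0, 1.0]
    - [40.0, 38.0, 5.0, 0.8]
frame_times: [0.0, 1.0, 2.0, 3.0, 4.0]
noise_sigma: 0.0
scheme: gradient
seed_density: 6
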