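# spiralcine

Simulation and reconstruction toolkit for spiral cardiac real-time MRI with a
spatio-temporal (2D+t) score-based diffusion prior.

The package covers the full chain:

- **`spiralcine.synthetic`** — seeded dynamic cardiac phantoms (contracting
  myocardial annulus, blood pool, papillary features, chest wall), smooth
  complex coil-sensitivity maps, max-magnitude normalization.
- **`spiralcine.spiral`** — Archimedean spiral trajectories (13 arms per
  real-time frame, 104-arm full coverage via an 8-state interleaved rotation
  scheme), non-uniform Fourier sampling of multi-coil data, DC self-gating
  and retrospective binning into segmented cine.
- **`spiralcine.gridding`** — GRAPPA operator gridding (GROG) with exact
  fractional-power coil-space shift operators, occupancy masks, an
  ESPIRiT-style coil-map estimator, and SENSE-style coil combination.
- **`spiralcine.operators`** — the Cartesian measurement operator
  `A = M F S`, its adjoint, central-crop embedding/extraction and the
  temporal-average reconstruction.
- **`spiralcine.nn`** / **`spiralcine.prior`** — a pure-NumPy U-Net with
  variable-length temporal attention and hand-written backward passes
  (training *and* the input-gradients needed by posterior sampling run
  without any deep-learning framework), the VE-SDE denoising-score-matching
  objective, EMA training loop and single-file checkpoints.  Disabling the
  temporal layers yields the per-frame 2D baseline.
- **`spiralcine.dps`** — diffusion-posterior-sampling reconstruction:
  reduced-step reverse chain initialized from a noise-perturbed temporal
  average, Tweedie denoising, residual-normalized likelihood gradients with
  frozen-periphery re-attachment, and independent 20-frame blocks.
- **`spiralcine.baselines`** — temporal-total-variation (exact per-pixel 1D
  TV prox, circular or linear boundary), low-rank-plus-sparse, zero-filled
  adjoint.
- **`spiralcine.evaluation`** / **`spiralcine.stats`** — retrospective
  undersampling of segmented references (13-arm and 7-arm "every second arm"
  variants), SSIM/PSNR/NRMSE on centered 120 px crops rescaled to [0, 1],
  benchmark harness, and a Friedman + pairwise Wilcoxon (Pratt, exact for
  n ≤ 25) + Bonferroni statistics report with exact small-sample modes.
- **`spiralcine.pipeline`** — desk-scale end-to-end experiment wiring used
  by the CLI and the test suite.

## CLI

```bash
spiralcine simulate phantom --config phantom.yaml --out phantom.h5
spiralcine simulate acquire --data phantom.h5 --out spiral.h5 --rotation-period 1
spiralcine gate --data spiral.h5 --n-phases 20 --out gating.json
spiralcine bin --data spiral.h5 --gating gating.json --out binned.h5
spiralcine grid grog --data spiral.h5 --grid-size 512 --out gridded.h5
spiralcine maps estimate --data gridded.h5 --out maps.h5
spiralcine prior train --manifest train.yaml --steps 1000 --out prior.npz
spiralcine recon dps --data gridded.h5 --maps maps.h5 --ckpt prior.npz --out out/
spiralcine recon ttv --data gridded.h5 --maps maps.h5 --out out/
spiralcine recon lrs --data gridded.h5 --maps maps.h5 --out out/
spiralcine recon zf  --data gridded.h5 --maps maps.h5 --out out/
spiralcine evaluate benchmark --out metrics.csv
spiralcine evaluate stats --csv metrics.csv --value ssim --out stats.json
```

`phantom.yaml` holds `PhantomConfig` fields (`grid_size`, `crop_size`,
`n_frames_per_cycle`, `n_cycles`, `contraction_amplitude`, `rr_jitter`,
`breathing_amplitude`, `n_coils`, `noise_sigma`, `seed`); `train.yaml` lists
phantom HDF5 files under an `inputs:` key.

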