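# petboot

Image-domain bootstrap resampling for 4-D dynamic PET image data, with
non-parametric residue mapping of tracer kinetics and the simulation
harness to validate bootstrap standard errors against replication truth.

## What it does

Dynamic PET studies (`N` voxels x `T` time frames) are modeled as

```
z_ij = x_j' alpha_i + sigma_i * phi_j * Q(eta_ij | kappa_ij)
```

where `eta` is a sub-ordinate Gaussian field, independent across frames
and spatially stationary (FFT-diagonalized spectral density), and `Q` is
a kappa-binned empirical quantile transform that adapts to the local
skewness of reconstructed data. Fitting every unknown of this model
allows replicate studies to be simulated directly in the image domain —
a bootstrap that does not need raw projection or list-mode data.

The package provides:

- **`petboot.study`** — containers for dynamic studies (NIfTI-1 + CSV
  schedules / input functions), VOI masks, and an HDF5 fit container.
  Voxels are linearized x-fastest; all times are minutes.
- **`petboot.basis`** — data-dependent temporal basis: recursive
  bisection shape clustering and GCV-guided backwards elimination, with
  a residue-modeling variant that always carries protected arterial
  input and Patlak (running-integral) columns.
- **`petboot.glm`** — estimation of all model unknowns: weighted least
  squares coefficients, alternating spatial/temporal/bin scale
  iterations, per-bin quantile tables, and the periodogram-based spatial
  spectral density; plus residual diagnostics.
- **`petboot.bootstrap`** — the three engines: image-domain (spectral
  coloring of white noise through the quantile transform),
  projection-domain (multinomial count resampling), and recycling
  (regenerating many coefficient replicates from a small retained set).
- **`petboot.kinetics`** — monotone step-residue fitting, non-negative
  voxel mapping, residue decomposition into vascular / in-distribution /
  extraction parts, kinetic maps (blood volume, distribution volume,
  flow, flux, mean transit time, extraction), the analytic
  two-compartment residue, and bootstrap SD maps / VOI percentile
  distributions.
- **`petboot.scanner`** — validation scanners: a 2-D attenuated
  parallel-beam Radon projector with Poisson counts and ramp-filtered
  FBP reconstruction, and a 1-D Poisson deconvolution model (Fourier
  multipliers `|nu|^-beta`) with least-squares and EM-ML reconstruction;
  phantom generators with two-compartment sub-TACs.
- **`petboot.evaluation`** — replication truth, through-origin
  calibration regressions, RMSE summaries, nested-grid ROI analysis, and
  the log-log relative-error model.
- **`petboot.workflows` / `petboot.cli`** — end-to-end experiments and
  the `petboot` command line.

## Command line

```bash
petboot simulate --mode 2d --tracer fdg --size 32 --n-frames 20 --seed 1 --out sim.h5
petboot fit --image study.nii --schedule frames.csv --aif aif.csv --out fit.h5
petboot bootstrap --fit fit.h5 --kind image --n-reps 25 --seed 1 --out boots.h5
petboot experiment --mode 1d --seed 1 --out results/
```

Exit codes: 0 success, 2 validation error, 3 numerical failure.

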