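# csmri

Compressed-sensing MRI reconstruction toolkit with a stroke-cohort clinical
analysis layer.

The imaging side generates piecewise-constant brain-like phantoms, simulates
noisy undersampled k-space acquisitions (variable-density random, radial,
Cartesian-line or full sampling masks), and reconstructs images by
total-variation L1 minimization, minimum-L2-variation solving, or a general
penalized (Lagrangian) solver with TV / L1 / wavelet / quadratic-smoothness
terms. Small explicit sensing systems come with exact sparse-recovery
theory: spark computation, k-sparse uniqueness certificates (unique iff
spark > 2k, with constructed witness pairs otherwise) and exhaustive L0
decoding.

The clinical side implements an early-neurological-deterioration (END)
classification rule on NIHSS score trajectories (baseline-dependent and
fixed-delta variants), 2x2 contingency statistics (proportions, Woolf
odds-ratio intervals, Pearson chi-square), a maximum-likelihood logistic
model fitted by IRLS, and a synthetic cohort generator anchored to the
packaged worked-example summary statistics.

## Library layout

| module                   | contents |
|--------------------------|----------|
| `csmri.phantom`          | ellipse phantoms, lesions, k-space simulation, sparse test signals |
| `csmri.sensing`          | sampling masks, Fourier operator, explicit `Theta = Pi @ Omega` systems, materialization |
| `csmri.recovery_theory`  | `spark`, `certify_uniqueness`, `l0_decode` (exhaustive, N <= 16) |
| `csmri.reconstruct`      | `reconstruct_l1_tv`, `reconstruct_l2`, `reconstruct_lagrangian`, `tv_seminorm`, `evaluate` (PSNR/SSIM/relative L2) |
| `csmri.clinical_end`     | END rules, contingency statistics, logistic IRLS, cohort simulation, worked-example report |
| `csmri.io`               | HDF5 bundles (schema 1), matrix CSV, cohort CSV, PNG/NIfTI export, JSON reports |

Conventions: unitary centred Fourier transform (`fft2c`/`ifft2c`), image
index (0, 0) top-left, masks stored zero-frequency-centred.

## CLI

One umbrella executable with subcommands; a JSON `--config` file can
preload options (flags override), and every run logs its resolved
configuration.

```bash
csmri phantom --size 64 --lesion --seed 1 -o phantom.h5
csmri acquire --mask vd-random --fraction 0.3 --noise 0 --seed 1 -i phantom.h5 -o acq.h5
csmri reconstruct --method l1tv --lam 0 -i acq.h5 -o recon.h5
csmri evaluate -i recon.h5 -r phantom.h5 --json metrics.json

csmri clinical simulate --n-det 36 --n-ctrl 151 --seed 1 -o cohort.csv
csmri clinical classify --rule baseline -i cohort.csv
csmri clinical analyze -i cohort.csv --json analysis.json
csmri clinical worked-example --json worked.json
```

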