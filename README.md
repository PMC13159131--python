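# smtpipe

A single-molecule tracking (SMT) analysis pipeline for membrane-receptor
diffusion, built around the workflow used to study the lateral mobility of
the pseudokinase receptor PTK7 on living pancreatic cells: TIRF movies of
sparsely labeled receptors are reduced to per-frame localizations, linked
into trajectories, and each trajectory is characterized by its
time-averaged mean squared displacement (TA-MSD), diffusion coefficient D,
anomalous exponent α, and motion mode (confined / Brownian / directed).
Population statistics (median D, mode fractions, group comparisons,
perturbation effect sizes) and dSTORM-style localization cluster analysis
complete the pipeline.

Because single-molecule microscopy data are rarely shareable, the package
ships a first-class **synthetic-data generator**: trajectories with known
ground truth in three motion modes, mixed populations calibrated to
published per-cell-line statistics, and a camera model that renders
movies with a pixel-integrated Gaussian PSF, Poisson noise, and
single-step photobleaching. Every analysis stage is therefore testable
end-to-end against ground truth.

## Model

For a 2-D trajectory sampled at interval Δt, the time-averaged MSD at lag
τ = nΔt is

    MSD(τ) = ⟨ |r(t+τ) − r(t)|² ⟩_t

For free (Brownian) diffusion MSD(τ) = 4Dτ + 4σ_loc², where σ_loc is the
localization precision. The anomalous exponent α is the slope of
log MSD vs log τ; each trajectory is classified by

    α < 0.7  → confined      0.7 ≤ α ≤ 1.3 → Brownian      α > 1.3 → directed

D is estimated from the short-lag slope (OLS over the first 4 lags,
D = slope/4) and refined with a mode-specific MSD model: the corral model
P·(1 − 0.99·e^(−3.4Dτ/P)) + c for confined motion and the drift model
4Dτ + (vτ)² + c for directed motion, so that D always measures the
short-time diffusivity rather than an artifact of confinement or drift.

Populations are summarized by the **median** D (the per-trajectory D
distribution is strongly right-skewed), compared by one-way ANOVA with
Tukey's HSD, and perturbations are quantified as the percent change of
the median D with a seeded percentile-bootstrap confidence interval.

## Worked example

Simulate 2000 trajectories from the metastasis-derived PaTu-8988t preset
(published pooled median D = 0.18 µm²/s, mode fractions 44/32/24) and run
the full analysis:

```bash
smtpipe simulate --preset PaTu-8988t --n-traj 2000 --seed 42 -o patu.csv
smtpipe run -i patu.csv -o out/ --seed 42
cat out/summary.json
```

```json
{
  "group_id": "patu",
  "n_traj": 2000,
  "median_D_um2_s": 0.16795270494126147,
  "D_iqr_um2_s": 0.1882182136232186,
  "mode_fractions": {
    "confined": 0.45,
    "brownian": 0.316,
    "directed": 0.234
  },
  "n_alpha_undefined": 0
}
```

The recovered pooled median (0.168 µm²/s) sits within 7% of the preset's
calibration target and the classified mode fractions land within ~1–2
percentage points of the 44/32/24 ground truth — the published
statistics re-measured through the full estimator chain on a finite
sample. `out/report.json` records the config hash,
seed, library versions, and a count ledger for every filtering stage.

Other subcommands expose individual stages (`render`, `detect`, `link`,
`msd`, `classify`, `summarize`, `compare`, `cluster`); all accept
`--config config.yaml` (flat key-value file, unknown keys rejected) and
`--seed`.

## Library use

```python
from smtpipe.simulate import cell_line_preset, simulate_population
from smtpipe.msd import fit_population, mode_fractions
import numpy as np

spec = cell_line_preset("hTERT-HPNE", n_traj=2000, seed=1)
fits, _ = fit_population(simulate_population(spec), spec.dt)
print(np.median([f.D for f in fits]), mode_fractions(fits)[0])
```

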