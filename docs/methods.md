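# Methods

This note documents the models, estimators, parameter choices, and known
limitations of smtpipe. Units are µm and seconds throughout; frames are
0-based; positions use a top-left origin with y increasing downward, and
pixel i spans [i·s, (i+1)·s) µm so the continuous pixel coordinate of a
point at x µm is x/s − 0.5.

## Trajectory generator

Each trajectory is a discrete 2-D random walk sampled at interval dt
(default 0.1 s, i.e. 10 Hz video rate) with independent per-axis Gaussian
steps of variance 2·D·dt, plus one of three mode-specific mechanisms:

- **Brownian** — the free walk.
- **Directed** — a constant drift v·dt per frame along a fixed heading
  (headings uniform on [0, 2π) across a population).
- **Confined** — the walk is reflected at a circle of radius R about the
  start point, by radial folding of any excursion beyond the boundary.
  Folding is exact to first order in step/R; in the strongly confined
  regime used by the presets (R ≈ 1.8 per-axis step s.d.) the stationary
  distribution deviates slightly from the uniform disk, which is why the
  closed-form plateau check (TA-MSD → R²) is run in the small-step
  regime (step ≪ R), where the discrete walk converges to continuum
  reflecting diffusion.

Independent Gaussian localization noise (s.d. sigma_loc per axis,
default 0.03 µm — typical for a bright organic dye under TIRF) is added
to every reported position. All randomness derives from one root seed;
each trajectory consumes its own child stream keyed by trajectory id, so
any subset of a population can be regenerated bit-identically.

### Populations and presets

A population draws each trajectory's mode from the requested fractions
and its D log-normally about the mode median with log-scale spread
sigma_log = 0.5 (per-trajectory D distributions in SMT data are broad
and right-skewed; 0.5 gives roughly a 3-fold interquartile spread).

Per-mode median D values keep the fixed ratio confined : Brownian :
directed = 0.5 : 1 : 1.5; the overall scale is solved so that the pooled
per-trajectory median D equals the target median of the preset. Because
the pooled median of the log-normal mixture scales linearly with the
overall scale factor, this calibration is an exact, deterministic
root-solve on the analytic mixture CDF — no simulation or caching is
involved.

Presets (fractions confined/Brownian/directed, pooled median D in
µm²/s): hTERT-HPNE 68/20/12, 0.07; MIA PaCa-2 58/24/18, 0.10; PANC-1
50/29/21, 0.13; PaTu-8988t 44/32/24, 0.18; PAAD-21010 (primary
patient-derived) uses the default 50/29/21 fractions — flagged
`fractions_unprinted`, since only its pooled median (0.11) is published
— at that published median.

### Mode-separation knobs

The corral radius and drift speed are not published; they are set as
dimensionless multiples of each trajectory's diffusive step:

    R = 1.25 · sqrt(4·D·dt)        v = 0.6 · sqrt(4·D / dt)

Both co-scale with sqrt(D) of the individual trajectory, so the *shape*
of each mode's MSD (and hence its α distribution) is invariant to the
log-normal D dispersion. The numerical factors were fixed once, by a
design simulation, at the point where (a) the three α distributions are
well separated at the default thresholds (per-mode recall ≈ 0.98–1.0 at
100 frames), and (b) the mode-specific D estimators below recover the
micro-diffusivity with per-mode median ratios of 0.92–0.99, so the
pooled fitted median tracks the calibrated ground-truth median. Stronger
confinement or drift makes the modes easier to classify but makes D
unrecoverable; weaker makes D trivial but collapses the α separation.
This trade-off is intrinsic to MSD analysis at 100-frame trajectories.

### Camera model

Movies are rendered at pixel size 0.107 µm (config) with an isotropic
Gaussian PSF of s.d. 0.1 µm integrated exactly over the pixel grid
(error-function model), an expected photon budget per emitter per frame
(default 300 over a background of 20 photons/px, peak SNR ≈ 10), and
per-pixel Poisson noise on signal + background. Photobleaching is
single-step: with per-frame probability `bleach_prob` an emitter turns
dark irreversibly, so the survival curve is geometric — the signature
used to validate single-fluorophore labeling. Output is 16-bit unsigned
TIFF plus a ground-truth table (frame, trajectory id, pixel and µm
positions, photons, alive flag).

## Localization

Detection: difference-of-Gaussians band-pass (σ and 2σ of the nominal
PSF), thresholded at 5× the robust (MAD-based) s.d. of the response;
3×3 local maxima above threshold become candidates. Each candidate is
refined by least-squares fitting of the pixel-integrated Gaussian plus a
constant offset in a window of half-width 3·psf_sigma; fits that
diverge, whose width leaves [0.5, 2]× the nominal PSF, or whose center
leaves the window are dropped rather than retried, keeping per-frame
output deterministic. Because the fit model equals the render model, the
localization bias on noiseless symmetric spots is below 10⁻³ px; with
noise the error is shot-noise-limited (~0.05–0.1 px at SNR 10).
Candidates closer than the fit-window half-width to the image border are
not fit (a ~0.4 µm frame of the field), which biases the density
estimate down by roughly 3% at a 25.6 µm field — inside the 10% QC
tolerance.

Density QC divides mean detections per frame (first 10 frames, before
appreciable bleaching) by the field area. Single-fluorophore validation
counts downward change-points in an aperture-photometry intensity trace
(circular aperture minus annulus-median background): recursive binary
segmentation on the mean accepts a split while the Gaussian-cost
improvement n·log(SSE₀/SSE₁) exceeds 3·log(n); accepted change-points
count as bleach steps only if the mean drops by more than 3× the local
noise s.d. (from the median absolute successive difference). The
penalty factor 3 holds the false-positive rate on constant-noise traces
well below 5%. Exactly one step validates a single fluorophore.

## Linking

Frame-to-frame correspondence minimizes the total squared displacement
over a bipartite assignment (Hungarian algorithm on an augmented matrix
with birth/death costs at r_max², gate r_max, default 2.5 µm ≈
4·sqrt(4·D·dt) at D = 1 µm²/s — per-step miss probability < 10⁻³ over
the D range of interest). Frame pairs with more than 500 candidates fall
back to greedy nearest-pair matching with a logged warning. A second
pass closes gaps: track ends are assigned to later track starts across
up to gap_max (default 1) missing frames, with cost d²/Δf (diffusive
scaling) and gate r_max·sqrt(Δf). Tracks shorter than min_len (default
20 frames — enough for 5 MSD lags at the N/4 cap) are discarded. No
merging/splitting and no motion-model prediction.

## MSD analysis and classification

TA-MSD at lag n averages squared displacements over all ordered pairs
(i, i+n); pairs spanning closed gaps contribute to the lag equal to
their true frame difference (implemented on a dense NaN-padded frame
grid, verified exactly against brute-force pair enumeration). The
default maximum lag is ⌊span/4⌋ to control pair-count noise.

- **D (generic)**: OLS of MSD on τ over the first 4 lags, D = slope/4;
  the intercept absorbs the localization-noise floor 4σ_loc²; negative
  slopes clamp D to 0 with a flag.
- **α**: OLS slope of log MSD on log τ over lags 1–10 (capped at N/4),
  dropping non-positive values; undefined (and excluded from mode
  fractions, but retained for D statistics) when fewer than 3 usable
  lags remain. For a 100-frame Brownian trajectory this estimator has
  an irreducible sampling s.d. of ≈ 0.11 — the dominant limit on
  classification sharpness (see Limitations).
- **Classification**: confined below 0.7, directed above 1.3, Brownian
  between; boundary values go to Brownian. A threshold-sweep utility
  reports mode fractions over the grid confined_max ∈ [0.5, 0.9] ×
  directed_min ∈ [1.1, 1.5] (step 0.1) and each fraction's maximum
  drift across the grid.
- **Mode-specific D refit**: after classification, confined
  trajectories are refit with the corral model
  P·(1 − A·e^(−4BDτ/P)) + c (A = 0.99, B = 0.85, the standard
  confined-diffusion MSD approximation for a circular domain), and
  directed trajectories with 4Dτ + (vτ)² + c (quadratic LS over the
  first 8 lags, where the diffusive term is still visible). Both fits
  use TA-MSD variance weights σ_n ∝ MSD_n·sqrt(n/(N−n+1)). Without
  these refits the plain short-lag slope underestimates confined D
  ~5-fold and overestimates directed D severalfold, making the pooled
  fitted-D distribution bimodal and its median both biased and
  unstable; with them the per-mode median fitted/true ratios are
  0.92–0.99. A failed refit falls back to the generic estimator.

## Population statistics

Group summaries use the median D and interquartile range over all fitted
trajectories and mode fractions over classified ones; the excluded
(α-undefined) count is always reported. The default QC floor is 1000
trajectories per group (overridable with a logged warning). Group
comparisons: one-way ANOVA F/p plus all pairwise Tukey HSD p-values.
Group-level correlations (e.g. median D vs a migration phenotype
measured externally — phenotype numbers are always supplied fixtures,
never computed here): Pearson r with two-sided p. Perturbation effect:
percent change of median D with a seeded percentile bootstrap (default
2000 resamples, 95% level). When the treated group is the same
trajectory ensemble under a deterministic rescaling (the simulated
antibody experiments), the bootstrap resamples trajectory indices
jointly (`paired=True`); independent resampling would ignore the pairing
and overstate the CI several-fold.

## Cluster analysis

DBSCAN (eps 0.05 µm, min_pts 10 — typical dSTORM scales) on localization
point patterns; per-cluster size is the radius of gyration (for an
isotropic Gaussian blob of s.d. σ, Rg = σ√2), with convex-hull area
reported alongside. Two conditions are compared by a two-sided
Mann–Whitney test on the radius distributions with a median-based
direction label. No drift correction and no blinking (multi-count)
correction.

## What the generator does and does not emulate

It emulates: video-rate TIRF sampling, sparse labeling (0.2 spots/µm²),
localization noise, Poisson camera statistics, single-step bleaching,
broad per-trajectory D dispersion, and three-mode mixtures calibrated to
published per-cell-line medians and fractions. It does not emulate:
hop/fence diffusion beyond a single corral, mode switching within a
trajectory, fluorophore blinking, EM gain, cell-edge geometry, or any
biology (ligand binding, receptor clustering dynamics). Passing tests
therefore certify the estimator chain under the stated noise model, not
the biological interpretation of any particular dataset.

## Numerical sizes used in tests

Unit and acceptance tests run populations of 2000 trajectories × 100
frames (the per-condition scale at which the published medians are
quoted against a ≥1000-trajectory floor), 10⁴-trajectory ensembles for
closed-form Monte-Carlo checks, 50-frame rendered movies at the QC
density, and 200-replicate null calibrations for the ANOVA type-I rate.

## Known limitations

- The α sampling noise at 100 frames (s.d. ≈ 0.11 for Brownian motion)
  leaves ~35–40% of Brownian-mode alphas outside (0.9, 1.1). Mode
  fractions at the default thresholds are accurate to a couple of
  percentage points because spill-overs into the confined and directed
  bins are small and partially cancel, but fractions measured at the
  extremes of the threshold-sweep grid drift by up to ~10–20 points ×
  the Brownian fraction. Robustness to threshold choice at this
  trajectory length therefore holds only in a narrower band around the
  defaults; sharper robustness requires longer trajectories.
- The confined-mode refit assumes a single circular corral; it is not a
  hop-diffusion estimator.
- The linker is a two-pass assignment without motion models; at
  densities well above 0.2 spots/µm² or D·dt approaching the
  nearest-neighbor spacing, identity swaps will grow.
- Pixelation, finite PSF sampling and the uint16 camera quantization are
  modeled, but read noise and gain are not; detection quality at very
  low SNR (< ~5) is untested.
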