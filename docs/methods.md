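# Methods

This note documents the models, the synthetic data generator, the
numerical choices, and the study conditions used by the test suite and
by `scripts/acceptance.py`.  All spatial quantities are degrees of
visual angle; x increases rightward, y upward, origin at fixation.

## Stimulus simulation

The stimulus is a disk of radius 0.8° (diameter 1.6°) whose center
follows a momentum random walk at 60 Hz:

    s(t+1) = s(t) + c · p(t),      p(t+1) = (p(t) + ε) / ‖p(t) + ε‖,

with step length c = 0.008°/frame (0.48°/s) and direction noise
ε ~ N(0, σ²_stim I), σ_stim = 0.1 per component.  The center is
confined to a 6.0°×6.0° square: when the provisional step would leave
the square on an axis, that component of p is negated *before* the
step is taken (corner hits negate both), so the walk is bound to the
edge rather than clipped.  Because p is kept at unit norm, every step
has length exactly c — a property the tests assert to 1e-9.  The disk
can therefore span a 7.6°×7.6° field.

The initial state is not part of the walk's definition; the package
defaults to s(0) = (0, 0) with a uniformly random initial direction,
both exposed in the configuration.

A run consists of an initial rest (32 s), four 240-s stimulus blocks
separated by 12-s rests, and a final 12-s rest (1040 s total); volumes
are sampled every TR = 2 s.  Each stimulus-block volume is assigned
the frame at the midpoint of its TR window — a single representative
position, unbiased for the 2-s window.  Rest periods contribute no
stimulus volumes; the trajectory is continuous across blocks and runs.
Measured activity is paired with the stimulus 4 s (two volumes)
earlier — the hemodynamic delay is handled as a pure shift, with no
response-function convolution (the stimulus moves slowly enough that
each volume has a well-defined position).  Two runs yield 960 fitting
volumes; three runs yield 1440 decoded volumes.

The binary indicator I(x, y; sx, sy) is rasterized on a grid of
0.1°-pixels (symmetric about fixation, extent ±3.8°): a pixel is 1 iff
its center lies strictly within the radius.  The 0.1° default matches
the granularity of the 60×60 decoding grid.  Note the raster is
binary, so individual overlap-integral entries carry a quadrature
jitter of up to a few percent at 0.1° (median well below 0.1%);
halving the pixel size quarters the typical error.

## Synthetic voxel populations

Each of six area presets (V1like … FFAlike) specifies: RF-center
scatter SDs (per axis), the linear eccentricity scaling of RF size
(σ = intercept + slope·eccentricity, floored at 0.1°), response noise
SD, baseline C₀ = 0 and gain C₁ = 1, and 200 voxels by default (the
range of per-area selected voxel counts in real data).  The presets
emulate three qualitative features of the real areas: mean RF size
increases strictly from the V1-like to the FFA-like preset; horizontal
center scatter is similar everywhere (SD 1.5°); vertical center
scatter narrows sharply in the two highest presets (0.5° and 0.375°,
i.e. 25% of horizontal for FFAlike).  Real per-area RF statistics are
published only as figure-level summaries, so the numeric values are
the package's own choices and are documented as qualitative emulation,
not reproduction.

Noise SDs (1.0 … 1.25 across presets, at gain 1) were chosen so that
fitted voxels land in the working fit-quality regime of pRF decoding
studies — in-sample fit correlations of selected voxels mostly in
0.2–0.45, with a V1-like population at the full 960-volume fitting
size showing median fit_r ≈ 0.28.

RF centers are drawn from a centered per-axis Gaussian truncated (by
rejection) to the 7.6°×7.6° span field.  Responses are the noiseless
overlap integral plus i.i.d. Gaussian noise per voxel and volume;
optionally a per-voxel, per-run linear drift is injected
(`drift_slope_sd`, default 0) to give the detrending stage realistic
work.  Per-run linear detrending (least-squares line removed per voxel
per run) is applied by default in the pipeline and can be disabled
(`detrend: false`); with zero injected drift and near-zero noise,
detrending's per-run offset removal would otherwise dominate the
almost-degenerate likelihood weights.

What the generator does *not* emulate: hemodynamic convolution,
spatially correlated voxel noise, physiological noise spectra, and
pRF-model mismatch (compressive or elliptical RFs, surround
suppression).  Passing tests therefore demonstrate correctness of the
estimation and decoding machinery and the population-geometry effects
under the model's own assumptions — not robustness to the model
violations present in real fMRI data.

## pRF fitting

For fixed (μx, μy, σ), the Gaussian likelihood is maximized in closed
form: (C₀, C₁) by ordinary least squares against the overlap template
and σ_noise by the RMS residual, so the profiled log-likelihood is a
monotone function of the template–data correlation.  The search over
(μx, μy, σ) is initialized on a regular grid (μ at 0.5° spacing over
±3.5°, σ ∈ {0.25, 0.5, 1, 2, 4}°) and the best grid point is refined
by Nelder–Mead in (μx, μy, log σ) — log-space keeps σ positive without
constraints, and there is no upper bound on σ.  This profiled scheme
is mathematically equivalent to the joint six-parameter maximization
but far better conditioned.  Simplex tolerances: xatol 1e-3, maxiter
200; the returned likelihood never falls below the best grid point
(the grid seed is kept if refinement fails to improve).  The optimizer
hot loop evaluates overlaps in single precision; final parameters and
reported likelihoods are recomputed in double precision.  C₁ is not
sign-constrained; the fit correlation (observed vs fitted amplitude)
is therefore nonnegative by construction and is computed in-sample on
the training runs.

Selection keeps voxels with |μx|, |μy| ≤ 3.8° and fit_r strictly
greater than 0.2.  Under cross-validation, fitting *and* selection are
redone per training fold, so held-out runs never inform selection.
Degenerate inputs: a constant amplitude series returns fit_r = 0 and
is never selected.

## Decoding

The ML decoder evaluates, for each of 60×60 candidate positions tiling
the 6.0°×6.0° center field (cell centers at 0.1° spacing — candidates
outside the field the center can occupy would be pointless), the
summed per-voxel Gaussian log-likelihood with position-independent
terms dropped; ties resolve to the lowest grid index (row-major, x
fastest).  The implementation reduces the scan to one matrix product
per volume batch; tests assert exact agreement with an exhaustive
per-point log-pdf scan.

The SVR decoder trains one epsilon-insensitive regression per axis
with kernel exp(−‖r₁−r₂‖²/N), N the voxel count, on amplitudes
z-scored per voxel with training-fold statistics (z-scoring makes the
kernel's 1/N scale meaningful across noise levels).  Hyperparameters
C = 1 and ε = 0.1 are standard defaults, exposed in the configuration.
SVR uses the same ML-selected voxel set.  Predictions are not clipped
to the field.

## Population analyses

Accuracy is the Pearson correlation between true and predicted
coordinates per axis, pooled over all cross-validation folds.  Group
comparisons operate on Fisher-z (atanh) transformed accuracies; RF
sizes and center SDs are compared raw.  Across-subject intervals are
t-based (mean ± t·SEM) — the standard choice at n = 5 subjects, and
swappable for a bootstrap.  Center spread is the sample SD (n−1) of
fitted centers per axis.

Voxel-count matching decodes with random subsets drawn without
replacement from the union of per-fold selected voxels; within each
fold the draw is intersected with that fold's selected set, so
requesting the whole pool reproduces the full-population accuracy
exactly.

The distance-exclusion analysis decodes each volume using only voxels
whose fitted RF center lies farther than a threshold from the true
stimulus position at that volume (horizontal accuracy only;
thresholds 0–4° in 0.5° steps by default — the range is a package
choice).  The resulting accuracy-vs-threshold curve is summarized by
least-squares fitting y(d) = A·exp(−d/τ) + B with multistart over τ
(the baseline term absorbs the far-threshold floor); a flat or
non-decaying curve is flagged unidentifiable rather than yielding a
meaningless τ.

## Pipeline and determinism

`run_experiment` composes the stages per simulated subject and area
preset: simulate → sample population → simulate responses → detrend →
fit + select per fold → decode (ML and/or SVR) → aggregate.  Per-stage
seeds are SHA-256 hashes of the master seed and stage labels, so
adding a stage never perturbs earlier streams, and identical
config + seed produce byte-identical artifacts (CSV tables and a
sorted-key JSON report; timings go to stderr only).

## Study conditions (tests and acceptance script)

Problem sizes are scaled for a single CPU:

* **Oracle checks** — decoder vs exhaustive scan on 50 random
  10-voxel instances (full 3600-point grid); fitter vs a fine-grid
  profiled-likelihood scan (0.2° centers × 10 log-spaced sizes) on 20
  single-voxel instances of 120 volumes.
* **Parameter recovery** — V1-like preset, 100 voxels, 960 fitting
  volumes (the full-design fitting size), preset noise (median fit_r
  ≈ 0.28).
* **RF-size invariance** — 10 replicates; 100 voxels with RF centers
  uniform over the ±3° field, σ = 1.0° vs 3.0°, noise SD 1.0; two
  runs of four blocks (480 training volumes per fold).  Trajectory,
  centers and noise realization are shared within a replicate so the
  contrast isolates RF size.  The invariance is a property of
  adequately fitted models: at substantially higher noise, small-σ
  models fit poorly and their decoding degrades first.
* **Anisotropy** and **distance-exclusion decay** — 10 replicates of
  100 voxels on a reduced schedule (two runs of one 240-s block);
  these are within-population ordinal contrasts that are robust to
  the reduced fitting size.
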