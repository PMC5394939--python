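# prfdecode

Visual areas high in the ventral stream respond with large receptive
fields (RFs), which is often taken to mean they discard information
about *where* an object is.  At the population level that conclusion
does not follow: if RF centers tile the visual field, theory predicts
that the position information carried by the population is largely
insensitive to RF size.  `prfdecode` is a simulation and analysis
package for testing exactly this question with fMRI-style population
data: it simulates a stimulus moving in a random orbit, generates
synthetic voxel populations whose RF geometry emulates six visual
areas (V1-like through FFA-like), fits a Gaussian population
receptive-field (pRF) model per voxel, decodes the stimulus position
from multivoxel amplitudes, and runs the population analyses that
summarize how accuracy depends on RF size and RF-center geometry.

It is aimed at computational neuroscientists who want a fully
synthetic, fully reproducible test bed for pRF-based encoding/decoding
analyses — every stage is driven by one seed and runs in minutes on a
laptop.

## The model

Stimulus: a disk of radius 0.8° whose center follows a momentum random
walk, s(t+1) = s(t) + c·p(t) with p(t+1) = (p(t)+ε)/‖p(t)+ε‖,
ε ~ N(0, σ²_stim·I), c = 0.008°/frame at 60 Hz, confined to a
6.0°×6.0° field by reflecting the direction component that would leave
the field.  Positions are sampled to one per 2-s fMRI volume.

Encoding: each voxel n has a six-parameter Gaussian pRF model

    r̂ₙ(t) = C₀ + C₁ ∫ exp(−((x−μₓ)² + (y−μᵧ)²)/2σ²) · I(x, y, t) dx dy,
    rₙ(t) ~ N(r̂ₙ(t), σ²_noise),

where I is the binary stimulus indicator.  The six constants are
fitted by maximum likelihood: (C₀, C₁, σ_noise) have closed-form
optima given (μₓ, μᵧ, σ), which are searched on a regular grid and
refined with a Nelder–Mead simplex.  Voxels are kept when the fitted
center lies in the 7.6°×7.6° span field and the fit correlation
exceeds 0.2.

Decoding: (i) maximum likelihood — the candidate position on a 60×60
grid maximizing Σₙ log p(rₙ | sx, sy) under the fitted models with
independent Gaussian noise; (ii) support-vector regression per axis
with kernel k(r₁, r₂) = exp(−‖r₁−r₂‖²/N), N the voxel count.  Both
run under leave-one-run-out cross-validation, and accuracy is the
Pearson correlation between true and predicted coordinates per axis.

## Worked example

```python
import prfdecode as p

# one V1-like area, 20 voxels, two short runs — runs in seconds
cfg = p.make_fixture("tiny", seed=3)
report = p.run_experiment(cfg, "out/")
sub = report["areas"]["V1like"]["subjects"][0]
print(f"selected voxels: {sub['n_selected']}")
print(f"mean fitted RF size: {sub['mean_sigma']:.3f} deg")
print(f"accuracy r (horizontal, vertical): "
      f"{sub['r_horizontal_ml']:.3f}, {sub['r_vertical_ml']:.3f}")
```

prints

```
selected voxels: 19
mean fitted RF size: 0.610 deg
accuracy r (horizontal, vertical): 0.655, 0.619
```

i.e. 19 of the 20 synthetic voxels pass selection, the mean fitted
Gaussian SD is close to the generating V1-like sizes (~0.6°), and at
this deliberately small voxel count the decoded trajectory correlates
with the true one at r ≈ 0.6–0.7 per axis (accuracy rises quickly
with more voxels and longer runs).  `out/` also receives the
per-volume positions, ground-truth parameters, fit tables and decoded
trajectories as CSV, plus the JSON report.

The same pipeline is scriptable from the shell:

```bash
prfdecode make-fixture --size tiny --seed 3 --out out/
prfdecode -v run-all --config out/config.json --out out/
```

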