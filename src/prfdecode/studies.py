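"""Canonical simulation studies over the synthetic populations.

Each function runs one complete, self-contained study at fixed
conditions — population geometry, noise level, run schedule — and
returns the measured quantities.  These are the testable forms of the
population-coding questions the package addresses:

* ``sigma_scale_invariance_study``: does tripling RF size change
  decoding accuracy when RF centers tile the field uniformly and noise
  is matched?  (Population-level position information is expected to be
  insensitive to RF size.)
* ``anisotropy_study``: does a population with narrow vertical
  RF-center scatter (the FFA-like geometry) lose vertical decoding
  accuracy specifically?
* ``distance_exclusion_study``: when voxels with RF centers near the
  stimulus are excluded, does accuracy collapse faster (smaller decay
  constant tau) for small-RF populations?
* ``parameter_recovery_study``: how well are RF centers and sizes
  recovered at the working fit-quality regime?
* ``ml_oracle_agreement`` / ``fit_bruteforce_check``: agreement of the
  vectorized decoder and the profiled fitter with exhaustive
  independent scans.

Problem sizes are scaled for a single CPU; see docs/methods.md.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._gaussian_overlap import DiskPixels, overlap_matrix_f32
from .decoding import (
    DecodingGrid,
    DecodingOptions,
    build_likelihood_table,
    cross_validate,
    decode_ml,
)
from .pipeline import derive_seed
from .population_analysis import (
    distance_exclusion_cv,
    fit_exponential_decay,
    prediction_accuracy,
)
from .prf_fit import PRFFitter, PRFParams, FitResult
from .stimulus_sim import (
    RunSchedule,
    StimulusSpec,
    TrajectoryConfig,
    VolumeSeries,
    frames_to_volumes,
    simulate_trajectory,
)
from .synthetic_population import (
    VoxelPopulation,
    make_area_presets,
    sample_population,
    simulate_responses,
)

__all__ = [
    "sigma_scale_invariance_study",
    "anisotropy_study",
    "distance_exclusion_study",
    "parameter_recovery_study",
    "ml_oracle_agreement",
    "fit_bruteforce_check",
]

#: Two runs of four 240-s blocks: 480 volumes/run, 960 fitting volumes —
#: the fitting size of the full design.
FULL_SCHEDULE = RunSchedule(
    initial_rest_s=0.0,
    block_duration_s=240.0,
    n_blocks=4,
    inter_block_rest_s=0.0,
    final_rest_s=0.0,
)

#: Two runs of one 240-s block: the reduced schedule for the
#: within-population comparative studies.
SHORT_SCHEDULE = RunSchedule(
    initial_rest_s=0.0,
    block_duration_s=240.0,
    n_blocks=1,
    inter_block_rest_s=0.0,
    final_rest_s=0.0,
)


def _volumes(schedule: RunSchedule, n_runs: int, seed: int) -> VolumeSeries:
    cfg = TrajectoryConfig(seed=seed)
    n_frames = int(n_runs * schedule.n_blocks * schedule.block_duration_s * 60)
    return frames_to_volumes(simulate_trajectory(cfg, n_frames), schedule, n_runs)


def _uniform_population(
    n: int, sigma: float, noise: float, seed: int, extent: float = 3.0
) -> VoxelPopulation:
    rng = np.random.default_rng(seed)
    return VoxelPopulation(
        area="uniform",
        C0=np.zeros(n),
        C1=np.ones(n),
        mu=rng.uniform(-extent, extent, size=(n, 2)),
        sigma=np.full(n, sigma),
        sigma_noise=np.full(n, noise),
    )


def _scaled(pop: VoxelPopulation, scale: float) -> VoxelPopulation:
    return VoxelPopulation(
        area=pop.area,
        C0=pop.C0,
        C1=pop.C1,
        mu=pop.mu,
        sigma=pop.sigma * scale,
        sigma_noise=pop.sigma_noise,
    )


def sigma_scale_invariance_study(
    seed: int = 0,
    n_seeds: int = 10,
    n_voxels: int = 100,
    sigma_base: float = 1.0,
    scale: float = 3.0,
    noise: float = 1.0,
) -> pd.DataFrame:
    """Decoding accuracy for matched populations with RF size x1 vs x`scale`.

    RF centers are uniform over the stimulus field and shared between
    the two populations of each replicate, as are the trajectory and
    the noise realization, so the contrast isolates RF size.  Fitting
    uses 480 training volumes per fold (two runs of four blocks).
    """
    opts = DecodingOptions()
    rows = []
    for i in range(n_seeds):
        volumes = _volumes(FULL_SCHEDULE, 2, derive_seed(seed, "inv-traj", i))
        pop = _uniform_population(
            n_voxels, sigma_base, noise, derive_seed(seed, "inv-pop", i)
        )
        row = {"seed": i}
        for label, sc in (("x1", 1.0), ("xs", scale)):
            population = _scaled(pop, sc) if sc != 1.0 else pop
            series = simulate_responses(
                population, volumes, opts.spec, derive_seed(seed, "inv-noise", i)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                acc = prediction_accuracy(
                    volumes, cross_validate(series, volumes, "ml", opts)
                )
            row[f"r_h_{label}"] = acc.r_horizontal
            row[f"r_v_{label}"] = acc.r_vertical
        rows.append(row)
    return pd.DataFrame(rows)


def anisotropy_study(
    seed: int = 0,
    n_seeds: int = 10,
    n_voxels: int = 100,
    presets: tuple[str, ...] = ("V1like", "FFAlike"),
) -> pd.DataFrame:
    """Horizontal vs vertical ML accuracy for area presets.

    Uses the reduced two-run schedule; one population and trajectory
    per replicate and preset.
    """
    opts = DecodingOptions()
    all_presets = {p.name: p for p in make_area_presets(n_voxels=n_voxels)}
    rows = []
    for i in range(n_seeds):
        volumes = _volumes(SHORT_SCHEDULE, 2, derive_seed(seed, "ani-traj", i))
        row = {"seed": i}
        for name in presets:
            pop = sample_population(
                all_presets[name], derive_seed(seed, "ani-pop", i, name)
            )
            series = simulate_responses(
                pop, volumes, opts.spec, derive_seed(seed, "ani-noise", i, name)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                acc = prediction_accuracy(
                    volumes, cross_validate(series, volumes, "ml", opts)
                )
            row[f"r_h_{name}"] = acc.r_horizontal
            row[f"r_v_{name}"] = acc.r_vertical
        rows.append(row)
    return pd.DataFrame(rows)


def distance_exclusion_study(
    seed: int = 0,
    n_seeds: int = 10,
    n_voxels: int = 100,
    scale: float = 3.0,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Decay constant tau of accuracy vs exclusion threshold, small vs
    large RFs (matched centers, matched noise)."""
    if thresholds is None:
        thresholds = np.arange(0.0, 4.01, 0.5)
    opts = DecodingOptions()
    preset = make_area_presets(n_voxels=n_voxels)[0]  # V1like geometry
    rows = []
    for i in range(n_seeds):
        volumes = _volumes(SHORT_SCHEDULE, 2, derive_seed(seed, "dec-traj", i))
        pop = sample_population(preset, derive_seed(seed, "dec-pop", i))
        row = {"seed": i}
        for label, sc in (("small", 1.0), ("large", scale)):
            population = _scaled(pop, sc) if sc != 1.0 else pop
            series = simulate_responses(
                population, volumes, opts.spec, derive_seed(seed, "dec-noise", i)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curve = distance_exclusion_cv(series, volumes, thresholds, opts)
                try:
                    fitted = fit_exponential_decay(curve)
                    row[f"tau_{label}"] = fitted.tau
                except (ValueError, RuntimeError):
                    row[f"tau_{label}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def parameter_recovery_study(
    seed: int = 0, n_voxels: int = 100
) -> dict[str, float]:
    """Center and size recovery on a V1-like population at 960 fitting
    volumes (the full-design fitting size)."""
    preset = make_area_presets(n_voxels=n_voxels)[0]
    volumes = _volumes(FULL_SCHEDULE, 2, derive_seed(seed, "rec-traj"))
    pop = sample_population(preset, derive_seed(seed, "rec-pop"))
    spec = StimulusSpec()
    series = simulate_responses(pop, volumes, spec, derive_seed(seed, "rec-noise"))
    fitter = PRFFitter(volumes, spec)
    fits = fitter.fit_many(series.amplitudes)
    center_err = [
        float(np.hypot(f.params.mu_x - m[0], f.params.mu_y - m[1]))
        for f, m in zip(fits, pop.mu)
    ]
    sigma_err = [
        abs(f.params.sigma - s) / s for f, s in zip(fits, pop.sigma)
    ]
    return {
        "median_center_error_deg": float(np.median(center_err)),
        "median_sigma_rel_error": float(np.median(sigma_err)),
        "median_fit_r": float(np.median([f.fit_r for f in fits])),
        "n_voxels": n_voxels,
        "n_volumes": volumes.n_volumes,
    }


def ml_oracle_agreement(seed: int = 0, n_instances: int = 50) -> dict[str, float]:
    """Fraction of random instances where the vectorized ML decoder
    equals an exhaustive per-grid-point Gaussian log-pdf scan."""
    rng = np.random.default_rng(derive_seed(seed, "mlorc"))
    spec = StimulusSpec()
    grid = DecodingGrid()
    pop = _uniform_population(10, 1.0, 0.5, derive_seed(seed, "mlorc-pop"))
    pop.sigma_noise[:] = rng.uniform(0.2, 1.0, pop.n_voxels)
    fits = [
        FitResult(
            PRFParams(pop.C0[i], pop.C1[i], pop.mu[i, 0], pop.mu[i, 1],
                      pop.sigma[i], pop.sigma_noise[i]),
            1.0,
            0.0,
        )
        for i in range(pop.n_voxels)
    ]
    table = build_likelihood_table(fits, grid, spec)
    agree = 0
    for _ in range(n_instances):
        activity = rng.normal(0.5, 1.0, size=pop.n_voxels)
        ours = decode_ml(activity, table)
        lls = stats.norm.logpdf(
            activity[None, :], loc=table.rhat.T, scale=table.sigma_noise[None, :]
        ).sum(axis=1)
        oracle = grid.positions[int(np.argmax(lls))]
        agree += bool(np.allclose(ours, oracle))
    return {"fraction_agree": agree / n_instances, "n_instances": n_instances}


def fit_bruteforce_check(seed: int = 0, n_instances: int = 20) -> dict[str, float]:
    """Compare profiled grid+simplex fitting with an exhaustive
    fine-grid profiled-likelihood scan on small instances.

    Returns the worst center discrepancy from the brute-force arg max
    and the fraction of instances where the fitted training likelihood
    is at least the brute-force maximum.
    """
    rng = np.random.default_rng(derive_seed(seed, "bforc"))
    spec = StimulusSpec()
    schedule = RunSchedule(
        initial_rest_s=0.0,
        block_duration_s=120.0,
        n_blocks=1,
        inter_block_rest_s=0.0,
        final_rest_s=0.0,
    )
    # fine oracle grid: 0.2 deg centers, log-spaced sizes
    mu_vals = np.arange(-2.4, 2.41, 0.2)
    gs = np.geomspace(0.4, 2.5, 10)
    gx, gy, gsig = np.meshgrid(mu_vals, mu_vals, gs, indexing="ij")
    cand_mu = np.column_stack([gx.ravel(), gy.ravel()])
    cand_sigma = gsig.ravel()
    max_center_diff = 0.0
    ll_wins = 0
    for k in range(n_instances):
        volumes = _volumes(schedule, 1, derive_seed(seed, "bforc-traj", k))
        true_mu = rng.uniform(-2, 2, size=2)
        true_sigma = rng.uniform(0.6, 1.8)
        pop = VoxelPopulation(
            "one",
            np.array([0.2]),
            np.array([1.0]),
            true_mu[None, :],
            np.array([true_sigma]),
            np.array([0.3]),
        )
        series = simulate_responses(
            pop, volumes, spec, derive_seed(seed, "bforc-noise", k)
        ).amplitudes[0]
        fitter = PRFFitter(volumes, spec)
        fit = fitter.fit(series)
        # brute force: profiled residual variance on the oracle grid
        pixels = DiskPixels.build(volumes.positions, spec, 0.8)
        design = overlap_matrix_f32(pixels, cand_mu, cand_sigma)
        r_c = series - series.mean()
        d_c = design - design.mean(axis=1, keepdims=True)
        denom = np.einsum("ij,ij->i", d_c, d_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr2 = np.where(
                denom > 0, (d_c @ r_c) ** 2 / (denom * (r_c @ r_c)), 0.0
            )
        best = int(np.argmax(corr2))
        resvar_oracle = float(np.var(series)) * (1.0 - corr2[best])
        resvar_fit = fit.params.sigma_noise**2
        diff = float(
            np.hypot(
                fit.params.mu_x - cand_mu[best, 0], fit.params.mu_y - cand_mu[best, 1]
            )
        )
        max_center_diff = max(max_center_diff, diff)
        ll_wins += bool(resvar_fit <= resvar_oracle * (1 + 1e-6))
    return {
        "max_center_diff_deg": max_center_diff,
        "fraction_ll_at_least_bruteforce": ll_wins / n_instances,
        "n_instances": n_instances,
    }
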