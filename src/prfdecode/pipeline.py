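"""End-to-end synthetic experiment orchestration and CLI.

One JSON-configurable pipeline runs the whole study per simulated
subject: simulate the stimulus random walk, sample a voxel population
per area preset, simulate and detrend responses, fit pRF models and
decode position under leave-one-run-out cross-validation, and
aggregate the population analyses into a JSON report.  All randomness
derives from one master seed; per-stage seeds are a stable hash of the
stage name, subject and area, so adding a stage never perturbs the
streams of earlier stages, and identical config + seed produce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from .decoding import DecodingGrid, DecodingOptions, cross_validate
from .population_analysis import (
    ci_across_subjects,
    center_spread,
    distance_exclusion_cv,
    fisher_z,
    fit_exponential_decay,
    one_way_f,
    paired_t,
    prediction_accuracy,
)
from .prf_fit import FitOptions, PRFFitter, fits_to_frame, select_voxels
from .stimulus_sim import (
    RunSchedule,
    StimulusSpec,
    TrajectoryConfig,
    VolumeSeries,
    frames_to_volumes,
    simulate_trajectory,
)
from .synthetic_population import (
    AreaPreset,
    VoxelTimeSeriesSet,
    linear_detrend,
    make_area_presets,
    sample_population,
    simulate_responses,
)

__all__ = ["ExperimentConfig", "run_experiment", "make_fixture", "derive_seed", "cli"]

log = logging.getLogger("prfdecode")


def derive_seed(master: int, *labels) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed."""
    key = ":".join([str(master), *map(str, labels)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    """Full configuration of one synthetic experiment."""

    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    schedule: RunSchedule = field(default_factory=RunSchedule)
    spec: StimulusSpec = field(default_factory=StimulusSpec)
    presets: list[AreaPreset] = field(default_factory=make_area_presets)
    fit: FitOptions = field(default_factory=FitOptions)
    grid: DecodingGrid = field(default_factory=DecodingGrid)
    svr_C: float = 1.0
    svr_epsilon: float = 0.1
    methods: tuple[str, ...] = ("ml", "svr")
    n_runs: int = 3
    n_subjects: int = 5
    seed: int = 0
    drift_slope_sd: float = 0.0
    detrend: bool = True
    exclusion_thresholds: tuple[float, ...] = ()
    subsample_voxels: int = 0
    subsample_repeats: int = 0

    def decoding_options(self) -> DecodingOptions:
        return DecodingOptions(
            grid=self.grid,
            fit=self.fit,
            spec=self.spec,
            svr_C=self.svr_C,
            svr_epsilon=self.svr_epsilon,
        )

    # -- JSON round trip ----------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {
            "trajectory": TrajectoryConfig,
            "schedule": RunSchedule,
            "spec": StimulusSpec,
            "fit": FitOptions,
            "grid": DecodingGrid,
        }
        # JSON has no tuples; coerce list-valued fields declared as tuples
        tuple_fields = {
            "trajectory": ("initial_position", "initial_direction"),
            "fit": ("sigma_grid",),
        }
        errors = []
        kwargs: dict = {}
        valid_fields = {f.name for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key not in valid_fields:
                errors.append(f"unknown field: {key}")
                continue
            try:
                if key in known:
                    value = dict(value)
                    for tf in tuple_fields.get(key, ()):
                        if isinstance(value.get(tf), list):
                            value[tf] = tuple(value[tf])
                    kwargs[key] = known[key](**value)
                elif key == "presets":
                    kwargs[key] = [AreaPreset(**p) for p in value]
                elif key in ("methods", "exclusion_thresholds"):
                    kwargs[key] = tuple(value)
                else:
                    kwargs[key] = value
            except (TypeError, ValueError) as exc:
                errors.append(f"{key}: {exc}")
        if errors:
            raise ValueError("invalid experiment config: " + "; ".join(errors))
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _simulate_subject_volumes(
    config: ExperimentConfig, subject: int
) -> VolumeSeries:
    traj_cfg = dataclasses.replace(
        config.trajectory, seed=derive_seed(config.seed, "trajectory", subject)
    )
    n_frames = int(
        config.n_runs
        * config.schedule.n_blocks
        * config.schedule.block_duration_s
        * traj_cfg.frame_rate
    )
    trajectory = simulate_trajectory(traj_cfg, n_frames)
    return frames_to_volumes(
        trajectory, config.schedule, config.n_runs, traj_cfg.frame_rate
    )


def simulate_subject_series(
    config: ExperimentConfig, subject: int, preset: AreaPreset
) -> tuple[VoxelTimeSeriesSet, VolumeSeries]:
    """Generate one subject x area synthetic dataset (detrended)."""
    volumes = _simulate_subject_volumes(config, subject)
    population = sample_population(
        preset, derive_seed(config.seed, "population", subject, preset.name)
    )
    series = simulate_responses(
        population,
        volumes,
        config.spec,
        derive_seed(config.seed, "responses", subject, preset.name),
        stimulus_radius=config.trajectory.stimulus_radius,
        drift_slope_sd=config.drift_slope_sd,
    )
    if config.detrend:
        series = linear_detrend(series)
    return series, volumes


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic experiment and write all artifacts.

    Writes per-subject volume tables, per-area ground truth and fits,
    decoded trajectories, and a single JSON report; returns the report
    dict.  Identical config + seed give byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    opts = config.decoding_options()
    t_start = time.time()
    per_area: dict[str, dict] = {p.name: {"subjects": []} for p in config.presets}

    for subject in range(config.n_subjects):
        volumes = _simulate_subject_volumes(config, subject)
        volumes.to_frame().to_csv(out / f"volumes_s{subject}.csv", index=False)
        for preset in config.presets:
            t0 = time.time()
            series, _ = simulate_subject_series(config, subject, preset)
            series.ground_truth.to_frame().to_csv(
                out / f"ground_truth_{preset.name}_s{subject}.csv", index=False
            )
            # one fit on all runs for RF summary statistics
            fitter = PRFFitter(volumes, config.spec, config.fit)
            fits = fitter.fit_many(series.amplitudes)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kept = select_voxels(fits, config.fit)
            fits_to_frame(fits, preset.name).to_csv(
                out / f"fits_{preset.name}_s{subject}.csv", index=False
            )
            entry: dict = {
                "subject": subject,
                "n_selected": len(kept),
                "mean_sigma": float(np.mean([f.params.sigma for f in kept]))
                if kept
                else np.nan,
            }
            if len(kept) >= 2:
                sd_x, sd_y = center_spread(kept)
                entry["center_sd_x"] = sd_x
                entry["center_sd_y"] = sd_y
            for method in config.methods:
                decoded = cross_validate(series, volumes, method, opts)
                decoded.to_frame(volumes).to_csv(
                    out / f"decoded_{preset.name}_s{subject}_{method}.csv",
                    index=False,
                )
                acc = prediction_accuracy(volumes, decoded)
                entry[f"r_horizontal_{method}"] = acc.r_horizontal
                entry[f"r_vertical_{method}"] = acc.r_vertical
            if config.exclusion_thresholds:
                curve = distance_exclusion_cv(
                    series,
                    volumes,
                    np.asarray(config.exclusion_thresholds),
                    opts,
                )
                curve.to_csv(
                    out / f"exclusion_{preset.name}_s{subject}.csv", index=False
                )
                try:
                    decay = fit_exponential_decay(curve)
                    entry["decay_tau"] = decay.tau
                    entry["decay_identifiable"] = decay.identifiable
                except (ValueError, RuntimeError):
                    entry["decay_tau"] = np.nan
            per_area[preset.name]["subjects"].append(entry)
            log.info(
                "subject %d area %s done in %.1f s (%d selected voxels)",
                subject,
                preset.name,
                time.time() - t0,
                len(kept),
            )

    report = {"config_seed": config.seed, "areas": {}, "group": {}}
    for name, block in per_area.items():
        subs = block["subjects"]
        area_summary: dict = {"subjects": subs}
        for key in ("mean_sigma", "center_sd_x", "center_sd_y"):
            vals = [s[key] for s in subs if key in s and np.isfinite(s[key])]
            if vals:
                area_summary[f"{key}_mean"] = float(np.mean(vals))
        for method in config.methods:
            for axis in ("horizontal", "vertical"):
                vals = [
                    s[f"r_{axis}_{method}"]
                    for s in subs
                    if np.isfinite(s.get(f"r_{axis}_{method}", np.nan))
                ]
                if vals:
                    area_summary[f"r_{axis}_{method}_mean"] = float(np.mean(vals))
                    if len(vals) >= 2:
                        lo, hi = ci_across_subjects(np.array(vals))
                        area_summary[f"r_{axis}_{method}_ci"] = [lo, hi]
        report["areas"][name] = area_summary

    # group statistics across areas (on Fisher-z accuracies) and sizes
    if len(config.presets) >= 2 and config.n_subjects >= 2:
        for method in config.methods:
            for axis in ("horizontal", "vertical"):
                groups = []
                for p in config.presets:
                    vals = [
                        s[f"r_{axis}_{method}"]
                        for s in per_area[p.name]["subjects"]
                        if np.isfinite(s.get(f"r_{axis}_{method}", np.nan))
                    ]
                    if len(vals) >= 2:
                        groups.append([fisher_z(min(v, 0.999999)) for v in vals])
                if len(groups) >= 2:
                    gs = one_way_f(groups)
                    report["group"][f"anova_{axis}_{method}"] = {
                        "F": gs.statistic,
                        "df": list(gs.df),
                        "p": gs.p_value,
                    }
        sigma_groups = [
            [s["mean_sigma"] for s in per_area[p.name]["subjects"]]
            for p in config.presets
        ]
        if all(len(g) >= 2 and np.all(np.isfinite(g)) for g in sigma_groups):
            gs = one_way_f(sigma_groups)
            report["group"]["anova_mean_sigma"] = {
                "F": gs.statistic,
                "df": list(gs.df),
                "p": gs.p_value,
            }
    for p in config.presets:
        for method in config.methods:
            h = [
                s.get(f"r_horizontal_{method}", np.nan)
                for s in per_area[p.name]["subjects"]
            ]
            v = [
                s.get(f"r_vertical_{method}", np.nan)
                for s in per_area[p.name]["subjects"]
            ]
            if len(h) >= 2 and np.all(np.isfinite(h)) and np.all(np.isfinite(v)):
                ts = paired_t(
                    np.array([fisher_z(min(x, 0.999999)) for x in h]),
                    np.array([fisher_z(min(x, 0.999999)) for x in v]),
                )
                report["group"][f"paired_t_hv_{p.name}_{method}"] = {
                    "t": float(ts.statistic),
                    "df": list(ts.df),
                    "p": float(ts.p_value),
                    "flag": ts.flag,
                }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=True)
    )
    log.info("experiment finished in %.1f s", time.time() - t_start)
    return report


def make_fixture(size: str = "tiny", seed: int = 0) -> ExperimentConfig:
    """Ready-made experiment configurations for tests and docs.

    ``tiny``: one V1-like area of 20 voxels, two short single-block
    runs — decodes in seconds.  ``small``: the full six-area,
    200-voxel, three-full-run layout of the study design.
    """
    if size == "tiny":
        return ExperimentConfig(
            schedule=RunSchedule(
                initial_rest_s=12.0,
                block_duration_s=240.0,
                n_blocks=1,
                inter_block_rest_s=0.0,
                final_rest_s=0.0,
            ),
            presets=[
                dataclasses.replace(make_area_presets(n_voxels=20)[0], noise_sd=0.2)
            ],
            n_runs=2,
            n_subjects=1,
            seed=seed,
            methods=("ml",),
        )
    if size == "small":
        return ExperimentConfig(seed=seed)
    raise ValueError("size must be 'tiny' or 'small'")


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log progress to stderr.")
def cli(verbose: bool) -> None:
    """Synthetic pRF position-decoding pipeline."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


def _load_config(path: str | None) -> ExperimentConfig:
    return ExperimentConfig.from_json(path) if path else ExperimentConfig()


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--subject", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def simulate(config_path: str | None, subject: int, out_path: str) -> None:
    """Write the per-volume stimulus positions for one subject."""
    config = _load_config(config_path)
    volumes = _simulate_subject_volumes(config, subject)
    volumes.to_frame().to_csv(out_path, index=False)
    click.echo(f"wrote {volumes.n_volumes} volumes to {out_path}", err=True)


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--series", "series_path", required=True, type=click.Path(exists=True))
@click.option("--volumes", "volumes_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def fit(config_path: str | None, series_path: str, volumes_path: str, out_path: str) -> None:
    """Fit pRF models to a long-format voxel series CSV."""
    config = _load_config(config_path)
    series, volumes = _read_series(series_path, volumes_path)
    fitter = PRFFitter(volumes, config.spec, config.fit)
    fits = fitter.fit_many(series.amplitudes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        select_voxels(fits, config.fit)
    fits_to_frame(fits).to_csv(out_path, index=False)
    click.echo(f"wrote {len(fits)} fits to {out_path}", err=True)


@cli.command()
@click.option("--method", type=click.Choice(["ml", "svr"]), default="ml")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--series", "series_path", required=True, type=click.Path(exists=True))
@click.option("--volumes", "volumes_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def decode(
    method: str, config_path: str | None, series_path: str, volumes_path: str, out_path: str
) -> None:
    """Cross-validated position decoding from a voxel series CSV."""
    config = _load_config(config_path)
    series, volumes = _read_series(series_path, volumes_path)
    decoded = cross_validate(series, volumes, method, config.decoding_options())
    decoded.to_frame(volumes).to_csv(out_path, index=False)
    acc = prediction_accuracy(volumes, decoded)
    click.echo(
        f"r_horizontal={acc.r_horizontal:.3f} r_vertical={acc.r_vertical:.3f}",
        err=True,
    )


@cli.command()
@click.option("--decoded", "decoded_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def analyze(decoded_path: str, out_path: str) -> None:
    """Per-axis accuracy of a decoded-trajectory CSV."""
    df = pd.read_csv(decoded_path)
    truth = VolumeSeries(df[["true_x", "true_y"]].to_numpy(), df["run"].to_numpy())
    from .decoding import DecodedTrajectory

    decoded = DecodedTrajectory(
        df[["pred_x", "pred_y"]].to_numpy(), df["run"].to_numpy(), df["method"].iloc[0]
    )
    acc = prediction_accuracy(truth, decoded)
    Path(out_path).write_text(
        json.dumps(
            {
                "r_horizontal": acc.r_horizontal,
                "r_vertical": acc.r_vertical,
                "n_volumes": acc.n_volumes,
            },
            indent=2,
            sort_keys=True,
        )
    )


@cli.command("run-all")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
def run_all(config_path: str | None, out_dir: str) -> None:
    """Run the full synthetic experiment."""
    run_experiment(_load_config(config_path), out_dir)


@cli.command("make-fixture")
@click.option("--size", type=click.Choice(["tiny", "small"]), default="tiny")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def make_fixture_cmd(size: str, seed: int, out_dir: str) -> None:
    """Write a fixture config and its experiment artifacts."""
    config = make_fixture(size, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    run_experiment(config, out)


def _read_series(
    series_path: str, volumes_path: str
) -> tuple[VoxelTimeSeriesSet, VolumeSeries]:
    vdf = pd.read_csv(volumes_path)
    volumes = VolumeSeries(
        vdf[["sx_deg", "sy_deg"]].to_numpy(), vdf["run"].to_numpy()
    )
    sdf = pd.read_csv(series_path)
    wide = sdf.pivot(index="voxel", columns="volume", values="amplitude")
    return (
        VoxelTimeSeriesSet(wide.to_numpy(), volumes.run_ids),
        volumes,
    )


if __name__ == "__main__":
    cli()
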