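"""Synthetic voxel populations with area-specific RF geometry.

Generates ground-truth voxel populations emulating six visual areas
(V1-like through FFA-like) and simulates their noisy responses to a
stimulus position sequence under the Gaussian-pRF forward model:

    r(t) = C0 + C1 * integral[ Gaussian(mu, sigma) * I(x, y, t) ] + noise,
    noise ~ N(0, sigma_noise^2), i.i.d. across voxels and volumes.

Area presets differ in RF size (growing from V1-like to FFA-like), in
the eccentricity scaling of RF size, and in the scatter of RF centers:
the higher-area analogs (LOC-like, FFA-like) have markedly narrower
vertical center scatter, the geometry behind the vertical-decoding
deficit the analysis stages probe.

The preset numbers are qualitative emulations of the real-area
statistics (those exist only as figure-level summaries), not
reproductions; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from ._gaussian_overlap import DiskPixels, overlap_matrix
from .stimulus_sim import StimulusSpec, VolumeSeries

__all__ = [
    "AreaPreset",
    "VoxelPopulation",
    "VoxelTimeSeriesSet",
    "make_area_presets",
    "sample_population",
    "simulate_responses",
    "linear_detrend",
    "load_voxel_series_nifti",
]

#: Half-width of the field the stimulus disk can span (center field
#: half-width + disk radius); RF centers are truncated to this square.
SPAN_HALF_WIDTH = 3.8


@dataclass(frozen=True)
class AreaPreset:
    """Generative parameters of one synthetic visual-area analog."""

    name: str
    n_voxels: int = 200
    center_sd_x: float = 1.5
    center_sd_y: float = 1.5
    size_intercept: float = 0.5  # degrees at eccentricity 0
    size_slope: float = 0.2  # degrees per degree of eccentricity
    size_floor: float = 0.1  # lower truncation of sigma, degrees
    noise_sd: float = 1.0
    baseline_C0: float = 0.0
    gain_C1: float = 1.0
    drift_slope_sd: float = 0.0  # optional per-run linear drift, units/volume

    def __post_init__(self) -> None:
        bad = []
        if self.n_voxels < 1:
            bad.append("n_voxels")
        if self.center_sd_x < 0 or self.center_sd_y < 0:
            bad.append("center_sd")
        if not self.size_floor > 0:
            bad.append("size_floor")
        if self.noise_sd < 0:
            bad.append("noise_sd")
        if bad:
            raise ValueError(f"invalid AreaPreset fields: {bad}")


@dataclass
class VoxelPopulation:
    """Ground-truth pRF constants for a set of voxels."""

    area: str
    C0: np.ndarray
    C1: np.ndarray
    mu: np.ndarray  # (n, 2)
    sigma: np.ndarray
    sigma_noise: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0) or np.any(self.sigma_noise < 0):
            raise ValueError("sigma must be > 0 and sigma_noise >= 0")

    @property
    def n_voxels(self) -> int:
        return len(self.sigma)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel": np.arange(self.n_voxels),
                "area": self.area,
                "C0": self.C0,
                "C1": self.C1,
                "mu_x": self.mu[:, 0],
                "mu_y": self.mu[:, 1],
                "sigma": self.sigma,
                "sigma_noise": self.sigma_noise,
            }
        )


@dataclass
class VoxelTimeSeriesSet:
    """Voxel-by-volume amplitude matrix with run labels."""

    amplitudes: np.ndarray  # (n_voxels, n_volumes)
    run_ids: np.ndarray
    ground_truth: VoxelPopulation | None = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.run_ids = np.asarray(self.run_ids)
        if self.amplitudes.shape[1] != len(self.run_ids):
            raise ValueError("amplitude columns must match run_ids length")

    @property
    def n_voxels(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.amplitudes.shape[1]

    def subset_voxels(self, idx: np.ndarray) -> "VoxelTimeSeriesSet":
        gt = self.ground_truth
        if gt is not None:
            gt = VoxelPopulation(
                area=gt.area,
                C0=gt.C0[idx],
                C1=gt.C1[idx],
                mu=gt.mu[idx],
                sigma=gt.sigma[idx],
                sigma_noise=gt.sigma_noise[idx],
            )
        return VoxelTimeSeriesSet(self.amplitudes[idx], self.run_ids, gt)

    def subset_volumes(self, mask: np.ndarray) -> "VoxelTimeSeriesSet":
        return VoxelTimeSeriesSet(
            self.amplitudes[:, mask], self.run_ids[mask], self.ground_truth
        )

    def to_frame(self) -> pd.DataFrame:
        v, t = np.meshgrid(
            np.arange(self.n_voxels), np.arange(self.n_volumes), indexing="ij"
        )
        return pd.DataFrame(
            {
                "voxel": v.ravel(),
                "volume": t.ravel(),
                "run": np.broadcast_to(self.run_ids, v.shape).ravel(),
                "amplitude": self.amplitudes.ravel(),
            }
        )


def make_area_presets(
    n_voxels: int = 200, noise_scale: float = 1.0
) -> list[AreaPreset]:
    """Six presets ordered V1-like to FFA-like.

    Mean RF size increases strictly along the order; the two
    higher-area analogs narrow the vertical scatter of RF centers.
    ``noise_scale`` multiplies every preset's response-noise SD.
    """
    base = [
        # name,      sd_x, sd_y, intercept, slope, noise_sd
        ("V1like", 1.5, 1.50, 0.40, 0.15, 1.00),
        ("V2like", 1.5, 1.40, 0.50, 0.18, 1.05),
        ("V3like", 1.5, 1.30, 0.62, 0.21, 1.10),
        ("V4like", 1.5, 1.10, 0.80, 0.25, 1.15),
        ("LOClike", 1.5, 0.50, 1.10, 0.30, 1.20),
        ("FFAlike", 1.5, 0.375, 1.40, 0.35, 1.25),
    ]
    return [
        AreaPreset(
            name=name,
            n_voxels=n_voxels,
            center_sd_x=sx,
            center_sd_y=sy,
            size_intercept=b0,
            size_slope=b1,
            noise_sd=ns * noise_scale,
        )
        for name, sx, sy, b0, b1, ns in base
    ]


def sample_population(preset: AreaPreset, seed: int) -> VoxelPopulation:
    """Draw a ground-truth voxel population from an area preset.

    RF centers come from a centered 2-D Gaussian with per-axis SDs,
    truncated (by rejection) to the span field; RF size follows the
    linear eccentricity scaling with a positive floor.
    """
    rng = np.random.default_rng(seed)
    n = preset.n_voxels
    mu = np.empty((n, 2))
    filled = 0
    while filled < n:
        draw = rng.normal(
            0.0, [preset.center_sd_x, preset.center_sd_y], size=(2 * (n - filled) + 8, 2)
        )
        ok = draw[np.all(np.abs(draw) <= SPAN_HALF_WIDTH, axis=1)]
        take = min(len(ok), n - filled)
        mu[filled : filled + take] = ok[:take]
        filled += take
    ecc = np.hypot(mu[:, 0], mu[:, 1])
    sigma = np.maximum(
        preset.size_floor, preset.size_intercept + preset.size_slope * ecc
    )
    return VoxelPopulation(
        area=preset.name,
        C0=np.full(n, preset.baseline_C0),
        C1=np.full(n, preset.gain_C1),
        mu=mu,
        sigma=sigma,
        sigma_noise=np.full(n, preset.noise_sd),
    )


def noiseless_responses(
    population: VoxelPopulation,
    volumes: VolumeSeries,
    spec: StimulusSpec,
    stimulus_radius: float = 0.8,
) -> np.ndarray:
    """Noise-free forward-model amplitudes, (n_voxels, n_volumes)."""
    pixels = DiskPixels.build(volumes.positions, spec, stimulus_radius)
    overlap = overlap_matrix(pixels, population.mu, population.sigma)
    return population.C0[:, None] + population.C1[:, None] * overlap


def simulate_responses(
    population: VoxelPopulation,
    volumes: VolumeSeries,
    spec: StimulusSpec,
    seed: int,
    stimulus_radius: float = 0.8,
    drift_slope_sd: float = 0.0,
) -> VoxelTimeSeriesSet:
    """Simulate noisy voxel responses to a stimulus position sequence.

    Amplitudes are the Gaussian-overlap forward model plus i.i.d.
    Gaussian noise with each voxel's ``sigma_noise``; optionally a
    per-voxel, per-run linear drift (slope drawn with SD
    ``drift_slope_sd`` per volume) is added so the detrending stage has
    realistic work.
    """
    if population.n_voxels == 0 or volumes.n_volumes == 0:
        raise ValueError("population and volumes must be non-empty")
    rng = np.random.default_rng(seed)
    clean = noiseless_responses(population, volumes, spec, stimulus_radius)
    noise = rng.normal(0.0, 1.0, size=clean.shape) * population.sigma_noise[:, None]
    amplitudes = clean + noise
    if drift_slope_sd > 0:
        for run in np.unique(volumes.run_ids):
            mask = volumes.run_ids == run
            t = np.arange(mask.sum())
            slopes = rng.normal(0.0, drift_slope_sd, size=population.n_voxels)
            amplitudes[:, mask] += slopes[:, None] * t[None, :]
    return VoxelTimeSeriesSet(
        amplitudes=amplitudes, run_ids=volumes.run_ids, ground_truth=population
    )


def linear_detrend(series: VoxelTimeSeriesSet) -> VoxelTimeSeriesSet:
    """Remove a per-voxel least-squares line within each run.

    Output amplitudes have zero mean per voxel per run.  Runs with
    fewer than 3 volumes are passed through unchanged with a warning.
    """
    out = series.amplitudes.copy()
    for run in np.unique(series.run_ids):
        mask = series.run_ids == run
        n = int(mask.sum())
        if n < 3:
            warnings.warn(f"run {run} has {n} volumes; detrend skipped")
            continue
        t = np.arange(n, dtype=float)
        t -= t.mean()
        block = out[:, mask]
        mean = block.mean(axis=1, keepdims=True)
        slope = (block @ t) / (t @ t)
        out[:, mask] = block - mean - slope[:, None] * t[None, :]
    return VoxelTimeSeriesSet(
        amplitudes=out, run_ids=series.run_ids, ground_truth=series.ground_truth
    )


def load_voxel_series_nifti(
    volume_paths: "list[str]",
    mask_path: str,
    run_ids: np.ndarray | None = None,
) -> VoxelTimeSeriesSet:
    """Load real voxel-by-volume amplitudes from 4-D NIfTI runs.

    ``volume_paths`` lists one 4-D functional image per run; voxels are
    taken where the 3-D ``mask_path`` image is nonzero, in C order.
    Stimulus positions per volume must be supplied separately (e.g. a
    volume-position table aligned by the caller).  Requires nibabel.
    """
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("loading NIfTI data requires nibabel") from exc
    mask = np.asanyarray(nib.load(mask_path).dataobj) != 0
    blocks = []
    labels = []
    for run, path in enumerate(volume_paths):
        data = np.asanyarray(nib.load(path).dataobj)
        if data.ndim != 4 or data.shape[:3] != mask.shape:
            raise ValueError(f"{path}: expected 4-D image matching the mask")
        blocks.append(data[mask, :])  # (n_voxels, n_volumes)
        labels.append(np.full(data.shape[3], run))
    run_labels = np.concatenate(labels) if run_ids is None else np.asarray(run_ids)
    return VoxelTimeSeriesSet(np.concatenate(blocks, axis=1), run_labels)
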