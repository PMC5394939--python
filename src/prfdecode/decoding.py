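"""Stimulus-position decoding from multivoxel amplitudes.

Two decoders are provided:

* Maximum likelihood (ML): with fitted pRF models and independent
  Gaussian noise across voxels, the log-likelihood of a candidate
  position (sx, sy) is, up to position-independent constants,
  ``-sum_n (r_n - rhat_n(sx, sy))^2 / (2 sigma_noise(n)^2)``.  The
  decoder evaluates it on a regular grid of candidate positions
  (default 60 x 60 over the field the stimulus center can occupy) and
  returns the arg max (ties broken by lowest grid index).

* Kernel support-vector regression (SVR): one epsilon-insensitive
  regression per output axis with the RBF kernel
  ``k(r1, r2) = exp(-||r1 - r2||^2 / N)``, N the number of voxels,
  trained on per-voxel z-scored amplitudes.

Both run under leave-one-run-out cross-validation: pRFs are fitted,
voxels selected, and (for SVR) the regression trained on the training
runs only; positions are predicted for the held-out run, and folds are
reassembled in original volume order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from ._gaussian_overlap import DiskPixels, overlap_matrix_f32
from .prf_fit import FitOptions, FitResult, PRFFitter, select_voxels
from .stimulus_sim import StimulusSpec, VolumeSeries
from .synthetic_population import VoxelTimeSeriesSet

__all__ = [
    "DecodingGrid",
    "LikelihoodTable",
    "SVRModel",
    "DecodedTrajectory",
    "DecodingOptions",
    "build_likelihood_table",
    "decode_ml",
    "decode_ml_batch",
    "train_svr",
    "predict_svr",
    "cross_validate",
]


@dataclass(frozen=True)
class DecodingGrid:
    """Regular grid of candidate stimulus-center positions.

    Cell centers tile the square the stimulus center can occupy
    (±extent).  Ordering is row-major with x varying fastest:
    index = iy * n_x + ix.
    """

    n_x: int = 60
    n_y: int = 60
    extent: float = 3.0

    @property
    def positions(self) -> np.ndarray:
        dx = 2.0 * self.extent / self.n_x
        dy = 2.0 * self.extent / self.n_y
        xs = (np.arange(self.n_x) + 0.5) * dx - self.extent
        ys = (np.arange(self.n_y) + 0.5) * dy - self.extent
        X, Y = np.meshgrid(xs, ys, indexing="xy")
        return np.column_stack([X.ravel(), Y.ravel()])

    @property
    def n_points(self) -> int:
        return self.n_x * self.n_y


@dataclass
class LikelihoodTable:
    """Predicted noiseless amplitude of each voxel at each grid point."""

    rhat: np.ndarray  # (n_voxels, n_grid)
    sigma_noise: np.ndarray  # (n_voxels,)
    grid: DecodingGrid


@dataclass
class SVRModel:
    """Per-axis kernel regressions mapping amplitude vectors to coordinates."""

    model_x: SVR
    model_y: SVR
    mean: np.ndarray  # per-voxel z-scoring parameters from training
    std: np.ndarray
    n_voxels: int
    train_predictions: np.ndarray  # (T_train, 2) in-sample predictions


@dataclass
class DecodedTrajectory:
    """Predicted positions per volume, with run labels and method tag."""

    positions: np.ndarray  # (n_volumes, 2)
    run_ids: np.ndarray
    method: str
    skipped_runs: list = field(default_factory=list)

    @property
    def n_volumes(self) -> int:
        return self.positions.shape[0]

    def to_frame(self, truth: VolumeSeries | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "volume": np.arange(self.n_volumes),
                "run": self.run_ids,
                "method": self.method,
                "pred_x": self.positions[:, 0],
                "pred_y": self.positions[:, 1],
            }
        )
        if truth is not None:
            df.insert(3, "true_x", truth.positions[:, 0])
            df.insert(4, "true_y", truth.positions[:, 1])
        return df


@dataclass(frozen=True)
class DecodingOptions:
    """Grid, fitting and SVR hyperparameters for the CV decoder."""

    grid: DecodingGrid = field(default_factory=DecodingGrid)
    fit: FitOptions = field(default_factory=FitOptions)
    spec: StimulusSpec = field(default_factory=StimulusSpec)
    svr_C: float = 1.0
    svr_epsilon: float = 0.1


def build_likelihood_table(
    fits: list[FitResult],
    grid: DecodingGrid,
    spec: StimulusSpec,
    radius: float = 0.8,
) -> LikelihoodTable:
    """Precompute every voxel's predicted amplitude at every grid point."""
    if not fits:
        raise ValueError("no selected voxels: cannot build a decoder")
    pixels = DiskPixels.build(grid.positions, spec, radius)
    mus = np.array([[f.params.mu_x, f.params.mu_y] for f in fits])
    sigmas = np.array([f.params.sigma for f in fits])
    overlap = overlap_matrix_f32(pixels, mus, sigmas)
    c0 = np.array([f.params.C0 for f in fits])
    c1 = np.array([f.params.C1 for f in fits])
    rhat = c0[:, None] + c1[:, None] * overlap
    sn = np.array([f.params.sigma_noise for f in fits])
    return LikelihoodTable(rhat=rhat, sigma_noise=sn, grid=grid)


def _ml_scores(activity: np.ndarray, table: LikelihoodTable) -> np.ndarray:
    """Position log-likelihoods up to per-volume constants, (T, n_grid)."""
    w = 1.0 / table.sigma_noise**2  # (n,)
    quad = 0.5 * (w @ (table.rhat**2))  # (G,)
    return (activity * w) @ table.rhat - quad[None, :]


def decode_ml(
    activity: np.ndarray, table: LikelihoodTable, grid: DecodingGrid | None = None
) -> tuple[float, float]:
    """ML-decode a single volume's amplitude vector.

    Returns the grid point maximizing the summed per-voxel Gaussian
    log-likelihood; ties resolve to the lowest grid index.
    """
    activity = np.asarray(activity, dtype=float)
    if activity.ndim != 1 or len(activity) != table.rhat.shape[0]:
        raise ValueError("activity length must equal the number of voxels")
    if not np.all(np.isfinite(activity)):
        raise ValueError("activity must be finite")
    grid = grid or table.grid
    scores = _ml_scores(activity[None, :], table)[0]
    return tuple(grid.positions[int(np.argmax(scores))])


def decode_ml_batch(
    activity: np.ndarray, table: LikelihoodTable, grid: DecodingGrid | None = None
) -> np.ndarray:
    """ML-decode many volumes at once; activity is (T, n_voxels)."""
    activity = np.asarray(activity, dtype=float)
    if not np.all(np.isfinite(activity)):
        raise ValueError("activity must be finite")
    grid = grid or table.grid
    scores = _ml_scores(activity, table)
    return grid.positions[np.argmax(scores, axis=1)]


def train_svr(
    train_activity: np.ndarray,
    train_positions: VolumeSeries,
    C: float = 1.0,
    epsilon: float = 0.1,
) -> SVRModel:
    """Train per-axis kernel SVRs on training amplitudes.

    ``train_activity`` is voxel-by-volume.  Amplitudes are z-scored per
    voxel with training statistics; the kernel is
    exp(-||r1 - r2||^2 / N) with N the voxel count (sklearn RBF with
    gamma = 1/N).
    """
    A = np.asarray(train_activity, dtype=float)
    if A.ndim != 2:
        raise ValueError("train_activity must be a voxel-by-volume matrix")
    n_voxels, T = A.shape
    if T < 2 or n_voxels < 1:
        raise ValueError("need >= 2 training volumes and >= 1 voxel")
    if T != train_positions.n_volumes:
        raise ValueError("training volumes and positions differ in length")
    mean = A.mean(axis=1)
    std = A.std(axis=1)
    std = np.where(std > 0, std, 1.0)
    Z = ((A - mean[:, None]) / std[:, None]).T  # (T, N)
    gamma = 1.0 / n_voxels
    model_x = SVR(kernel="rbf", gamma=gamma, C=C, epsilon=epsilon)
    model_y = SVR(kernel="rbf", gamma=gamma, C=C, epsilon=epsilon)
    model_x.fit(Z, train_positions.positions[:, 0])
    model_y.fit(Z, train_positions.positions[:, 1])
    train_pred = np.column_stack([model_x.predict(Z), model_y.predict(Z)])
    return SVRModel(
        model_x=model_x,
        model_y=model_y,
        mean=mean,
        std=std,
        n_voxels=n_voxels,
        train_predictions=train_pred,
    )


def predict_svr(
    model: SVRModel, activity: np.ndarray, run_ids: np.ndarray | None = None
) -> DecodedTrajectory:
    """Predict positions for a voxel-by-volume amplitude matrix.

    Predictions are not clipped to the stimulus field.
    """
    A = np.asarray(activity, dtype=float)
    if A.ndim != 2 or A.shape[0] != model.n_voxels:
        raise ValueError("activity voxel count must match the trained model")
    Z = ((A - model.mean[:, None]) / model.std[:, None]).T
    pred = np.column_stack([model.model_x.predict(Z), model.model_y.predict(Z)])
    if run_ids is None:
        run_ids = np.zeros(pred.shape[0], dtype=int)
    return DecodedTrajectory(positions=pred, run_ids=np.asarray(run_ids), method="SVR")


def cross_validate(
    series: VoxelTimeSeriesSet,
    volumes: VolumeSeries,
    method: str = "ml",
    options: DecodingOptions | None = None,
) -> DecodedTrajectory:
    """Leave-one-run-out decoding of every volume.

    For each fold, pRF models are fitted and voxels selected on the
    training runs only (SVR additionally trains on those runs using the
    ML-selected voxel set); the held-out run is then decoded.  Folds
    with no selected voxels are skipped (their predictions are NaN) and
    recorded in ``skipped_runs``.
    """
    method = method.lower()
    if method not in ("ml", "svr"):
        raise ValueError("method must be 'ml' or 'svr'")
    opts = options or DecodingOptions()
    runs = volumes.runs
    if len(runs) < 2:
        raise ValueError("cross-validation requires at least 2 runs")
    pred = np.full((volumes.n_volumes, 2), np.nan)
    skipped = []
    for test_run in runs:
        test_mask = volumes.run_ids == test_run
        train_mask = ~test_mask
        train_volumes = volumes.subset(train_mask)
        fitter = PRFFitter(train_volumes, opts.spec, opts.fit)
        fits = fitter.fit_many(series.amplitudes[:, train_mask])
        kept_idx = [i for i, f in enumerate(select_and_flag(fits, opts.fit)) if f]
        if not kept_idx:
            warnings.warn(f"fold with test run {test_run}: no selected voxels; skipped")
            skipped.append(test_run)
            continue
        kept_fits = [fits[i] for i in kept_idx]
        if method == "ml":
            table = build_likelihood_table(
                kept_fits, opts.grid, opts.spec, opts.fit.stimulus_radius
            )
            pred[test_mask] = decode_ml_batch(
                series.amplitudes[np.ix_(kept_idx, np.flatnonzero(test_mask))].T, table
            )
        else:
            model = train_svr(
                series.amplitudes[np.ix_(kept_idx, np.flatnonzero(train_mask))],
                train_volumes,
                C=opts.svr_C,
                epsilon=opts.svr_epsilon,
            )
            out = predict_svr(
                model, series.amplitudes[np.ix_(kept_idx, np.flatnonzero(test_mask))]
            )
            pred[test_mask] = out.positions
    return DecodedTrajectory(
        positions=pred,
        run_ids=volumes.run_ids,
        method=method.upper(),
        skipped_runs=skipped,
    )


def select_and_flag(fits: list[FitResult], options: FitOptions) -> list[bool]:
    """Selection mask over fits (wraps :func:`select_voxels` flags)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        select_voxels(fits, options)
    return [f.selected for f in fits]
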