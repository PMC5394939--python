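"""Population-level summaries of fitting and decoding results.

Covers per-axis prediction accuracy (Pearson correlation between true
and predicted coordinates), Fisher z-transforms for group statistics,
RF-center spread, accuracy with matched voxel counts (random
subsampling), the distance-exclusion analysis (decoding with only the
voxels whose RF centers are farther than a threshold from the current
stimulus position) and the exponential-decay fit summarizing how fast
accuracy falls as near-stimulus voxels are removed, plus the standard
group statistics (one-way ANOVA F, paired t, t-based CIs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .decoding import (
    DecodedTrajectory,
    DecodingOptions,
    build_likelihood_table,
    _ml_scores,
)
from .prf_fit import FitResult, PRFFitter, select_voxels
from .stimulus_sim import VolumeSeries
from .synthetic_population import VoxelTimeSeriesSet

__all__ = [
    "AccuracyResult",
    "DecayFit",
    "GroupStats",
    "prediction_accuracy",
    "fisher_z",
    "center_spread",
    "subsample_accuracy",
    "distance_exclusion_curve",
    "distance_exclusion_cv",
    "fit_exponential_decay",
    "one_way_f",
    "paired_t",
    "ci_across_subjects",
    "plot_accuracy_by_area",
    "plot_center_scatter",
    "plot_decay_curves",
]


@dataclass
class AccuracyResult:
    """Per-axis Pearson accuracy of a decoded trajectory."""

    r_horizontal: float
    r_vertical: float
    n_volumes: int


@dataclass
class DecayFit:
    """Exponential fit y(d) = amplitude * exp(-d / tau) + baseline."""

    tau: float
    amplitude: float
    baseline: float
    residual_sse: float
    identifiable: bool = True


@dataclass
class GroupStats:
    statistic: float
    df: tuple
    p_value: float
    flag: str = ""


def prediction_accuracy(
    truth: VolumeSeries, decoded: DecodedTrajectory
) -> AccuracyResult:
    """Per-axis correlation between true and predicted positions.

    Volumes with NaN predictions (skipped folds) are excluded.  A
    zero-variance prediction axis yields NaN with a warning.
    """
    if truth.n_volumes != decoded.n_volumes:
        raise ValueError("truth and decoded lengths differ")
    ok = np.all(np.isfinite(decoded.positions), axis=1)
    t = truth.positions[ok]
    p = decoded.positions[ok]
    if len(t) < 3:
        raise ValueError("need at least 3 predicted volumes")
    rs = []
    for axis in range(2):
        if np.std(p[:, axis]) == 0 or np.std(t[:, axis]) == 0:
            warnings.warn(f"zero-variance axis {axis}: correlation undefined")
            rs.append(np.nan)
        else:
            rs.append(float(np.corrcoef(t[:, axis], p[:, axis])[0, 1]))
    return AccuracyResult(r_horizontal=rs[0], r_vertical=rs[1], n_volumes=len(t))


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform of a correlation: atanh(r)."""
    r = float(r)
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    return float(np.arctanh(r))


def center_spread(fits: list[FitResult]) -> tuple[float, float]:
    """Sample SD (n-1 denominator) of fitted RF centers per axis."""
    if len(fits) < 2:
        raise ValueError("need at least 2 voxels")
    mx = np.array([f.params.mu_x for f in fits])
    my = np.array([f.params.mu_y for f in fits])
    return float(np.std(mx, ddof=1)), float(np.std(my, ddof=1))


def subsample_accuracy(
    series: VoxelTimeSeriesSet,
    volumes: VolumeSeries,
    n_voxels: int,
    n_repeats: int,
    seed: int,
    method: str = "ml",
    options: DecodingOptions | None = None,
) -> AccuracyResult:
    """Mean accuracy over repeated decoding with random voxel subsets.

    The eligible pool is the union of per-fold selected voxels from one
    shared cross-validated fit; each repeat draws ``n_voxels`` of them
    without replacement and decodes every fold with the drawn voxels
    (intersected with that fold's selected set).  Requesting the whole
    pool reproduces the full-population accuracy exactly.
    """
    opts = options or DecodingOptions()
    runs = volumes.runs
    folds = []
    for test_run in runs:
        test_mask = volumes.run_ids == test_run
        train_mask = ~test_mask
        fitter = PRFFitter(volumes.subset(train_mask), opts.spec, opts.fit)
        fits = fitter.fit_many(series.amplitudes[:, train_mask])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            select_voxels(fits, opts.fit)
        folds.append((test_mask, fits, np.array([f.selected for f in fits])))
    pool = np.flatnonzero(np.any([sel for _, _, sel in folds], axis=0))
    if n_voxels > len(pool):
        raise ValueError(f"n_voxels={n_voxels} exceeds the {len(pool)} selected voxels")
    rng = np.random.default_rng(seed)
    rh, rv = [], []
    for _ in range(n_repeats):
        chosen = np.zeros(series.n_voxels, dtype=bool)
        chosen[rng.choice(pool, size=n_voxels, replace=False)] = True
        pred = np.full((volumes.n_volumes, 2), np.nan)
        for test_mask, fits, sel in folds:
            use = np.flatnonzero(chosen & sel)
            if len(use) == 0:
                continue
            table = build_likelihood_table(
                [fits[i] for i in use], opts.grid, opts.spec, opts.fit.stimulus_radius
            )
            act = series.amplitudes[np.ix_(use, np.flatnonzero(test_mask))].T
            scores = _ml_scores(act, table)
            pred[test_mask] = opts.grid.positions[np.argmax(scores, axis=1)]
        acc = prediction_accuracy(
            volumes, DecodedTrajectory(pred, volumes.run_ids, "ML")
        )
        rh.append(acc.r_horizontal)
        rv.append(acc.r_vertical)
    return AccuracyResult(
        r_horizontal=float(np.mean(rh)),
        r_vertical=float(np.mean(rv)),
        n_volumes=volumes.n_volumes,
    )


def distance_exclusion_curve(
    fits: list[FitResult],
    series: VoxelTimeSeriesSet,
    volumes: VolumeSeries,
    thresholds: np.ndarray,
    options: DecodingOptions | None = None,
) -> pd.DataFrame:
    """Horizontal accuracy when near-stimulus RFs are excluded per volume.

    For each threshold, each volume is decoded using only the voxels
    whose fitted RF center is farther than the threshold from the true
    stimulus position at that volume.  Volumes left with no voxels are
    skipped and counted.  ``fits`` must align with the rows of
    ``series`` (the caller is responsible for train/test separation).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0) or thresholds[0] != 0:
        raise ValueError("thresholds must be ascending and start at 0")
    opts = options or DecodingOptions()
    table = build_likelihood_table(
        fits, opts.grid, opts.spec, opts.fit.stimulus_radius
    )
    centers = np.array([[f.params.mu_x, f.params.mu_y] for f in fits])
    dists = np.linalg.norm(
        centers[None, :, :] - volumes.positions[:, None, :], axis=2
    )  # (T, n_voxels)
    act = series.amplitudes.T  # (T, n)
    w = 1.0 / table.sigma_noise**2
    rows = []
    for thr in thresholds:
        keep = dists > thr  # (T, n)
        # masked ML score: only surviving voxels contribute
        wk = keep * w[None, :]
        scores = (act * wk) @ table.rhat - 0.5 * (wk @ (table.rhat**2))
        usable = keep.any(axis=1)
        if usable.sum() < 3:
            rows.append(
                {
                    "threshold": thr,
                    "r_horizontal": np.nan,
                    "n_used": int(usable.sum()),
                    "n_skipped": int((~usable).sum()),
                }
            )
            continue
        pred_x = opts.grid.positions[np.argmax(scores[usable], axis=1), 0]
        true_x = volumes.positions[usable, 0]
        r = float(np.corrcoef(true_x, pred_x)[0, 1])
        rows.append(
            {
                "threshold": thr,
                "r_horizontal": r,
                "n_used": int(usable.sum()),
                "n_skipped": int((~usable).sum()),
            }
        )
    return pd.DataFrame(rows)


def distance_exclusion_cv(
    series: VoxelTimeSeriesSet,
    volumes: VolumeSeries,
    thresholds: np.ndarray,
    options: DecodingOptions | None = None,
) -> pd.DataFrame:
    """Leakage-free distance-exclusion curve under leave-one-run-out CV.

    Fits and selects voxels per training fold, applies the per-volume
    exclusion on the held-out run, and pools predictions across folds
    before computing horizontal accuracy per threshold.
    """
    opts = options or DecodingOptions()
    thresholds = np.asarray(thresholds, dtype=float)
    pred_x = {float(t): np.full(volumes.n_volumes, np.nan) for t in thresholds}
    for test_run in volumes.runs:
        test_mask = volumes.run_ids == test_run
        train_mask = ~test_mask
        fitter = PRFFitter(volumes.subset(train_mask), opts.spec, opts.fit)
        fits = fitter.fit_many(series.amplitudes[:, train_mask])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept = select_voxels(fits, opts.fit)
        if not kept:
            continue
        idx = np.flatnonzero([f.selected for f in fits])
        table = build_likelihood_table(
            [fits[i] for i in idx], opts.grid, opts.spec, opts.fit.stimulus_radius
        )
        centers = np.array([[f.params.mu_x, f.params.mu_y] for f in kept])
        tv = volumes.subset(test_mask)
        dists = np.linalg.norm(centers[None, :, :] - tv.positions[:, None, :], axis=2)
        act = series.amplitudes[np.ix_(idx, np.flatnonzero(test_mask))].T
        w = 1.0 / table.sigma_noise**2
        where = np.flatnonzero(test_mask)
        for thr in thresholds:
            keep = dists > thr
            wk = keep * w[None, :]
            scores = (act * wk) @ table.rhat - 0.5 * (wk @ (table.rhat**2))
            usable = keep.any(axis=1)
            px = np.full(len(usable), np.nan)
            if usable.any():
                px[usable] = opts.grid.positions[
                    np.argmax(scores[usable], axis=1), 0
                ]
            pred_x[float(thr)][where] = px
    rows = []
    for thr in thresholds:
        px = pred_x[float(thr)]
        ok = np.isfinite(px)
        if ok.sum() >= 3 and np.std(px[ok]) > 0:
            r = float(np.corrcoef(volumes.positions[ok, 0], px[ok])[0, 1])
        else:
            r = np.nan
        rows.append(
            {
                "threshold": float(thr),
                "r_horizontal": r,
                "n_used": int(ok.sum()),
                "n_skipped": int((~ok).sum()),
            }
        )
    return pd.DataFrame(rows)


def fit_exponential_decay(curve: pd.DataFrame) -> DecayFit:
    """Fit y(d) = amplitude * exp(-d/tau) + baseline by least squares.

    ``curve`` has columns (threshold, r_horizontal); NaN rows are
    dropped.  Multistart over tau initial values; a flat or
    non-decreasing curve is flagged unidentifiable (tau is then
    meaningless and should not be interpreted).
    """
    d = curve["threshold"].to_numpy(dtype=float)
    y = curve["r_horizontal"].to_numpy(dtype=float)
    ok = np.isfinite(y)
    d, y = d[ok], y[ok]
    if len(d) < 4:
        raise ValueError("need at least 4 points to fit a decay")

    def model(x, a, tau, b):
        return a * np.exp(-x / tau) + b

    span = max(d.max() - d.min(), 1e-9)
    best = None
    for tau0 in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
        try:
            popt, _ = curve_fit(
                model,
                d,
                y,
                p0=[max(y[0] - y[-1], 1e-3), tau0, y[-1]],
                bounds=([-np.inf, 1e-6, -np.inf], [np.inf, 100 * span, np.inf]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - model(d, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise RuntimeError("decay fit failed for all starts")
    (a, tau, b), sse = best
    flat_scale = max(abs(y).max(), 1e-12)
    identifiable = abs(a) > 1e-3 * flat_scale and y[0] > y[-1]
    return DecayFit(
        tau=float(tau),
        amplitude=float(a),
        baseline=float(b),
        residual_sse=sse,
        identifiable=bool(identifiable),
    )


def one_way_f(groups: list[np.ndarray]) -> GroupStats:
    """One-way ANOVA F across groups of scalars."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    f, p = stats.f_oneway(*arrs)
    df_between = len(arrs) - 1
    df_within = sum(len(a) for a in arrs) - len(arrs)
    if not np.isfinite(f):  # all values identical in every group
        f, p = 0.0, 1.0
    return GroupStats(statistic=float(f), df=(df_between, df_within), p_value=float(p))


def paired_t(a: np.ndarray, b: np.ndarray) -> GroupStats:
    """Paired t test on the per-subject differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("a and b must have equal length >= 2")
    diff = a - b
    sd = np.std(diff, ddof=1)
    n = len(diff)
    if sd == 0:
        return GroupStats(
            statistic=np.inf if diff.mean() != 0 else 0.0,
            df=(n - 1,),
            p_value=np.nan if diff.mean() != 0 else 1.0,
            flag="zero-variance differences",
        )
    t = float(diff.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return GroupStats(statistic=t, df=(n - 1,), p_value=p)


def ci_across_subjects(
    values: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """t-based confidence interval for the across-subject mean."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    m = values.mean()
    sem = np.std(values, ddof=1) / np.sqrt(n)
    q = stats.t.ppf(0.5 + level / 2.0, n - 1)
    return float(m - q * sem), float(m + q * sem)


# ---------------------------------------------------------------------------
# figure output (optional; requires matplotlib)
# ---------------------------------------------------------------------------


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_accuracy_by_area(
    area_names: list[str],
    r_horizontal: np.ndarray,
    r_vertical: np.ndarray,
    path: str,
) -> None:
    """Line plot of per-area mean decoding accuracy, one line per axis."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    x = np.arange(len(area_names))
    ax.plot(x, r_horizontal, "o-", color="black", label="horizontal")
    ax.plot(x, r_vertical, "o-", color="gray", label="vertical")
    ax.set_xticks(x, area_names, rotation=30)
    ax.set_ylabel("accuracy (r)")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_center_scatter(fits: list[FitResult], path: str, title: str = "") -> None:
    """Scatter of fitted RF centers over the span field."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.scatter(
        [f.params.mu_x for f in fits],
        [f.params.mu_y for f in fits],
        s=12,
        alpha=0.6,
        edgecolors="none",
    )
    ax.set_xlim(-3.8, 3.8)
    ax.set_ylim(-3.8, 3.8)
    ax.set_xlabel("mu_x (deg)")
    ax.set_ylabel("mu_y (deg)")
    ax.set_title(title)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_decay_curves(curves: dict, path: str) -> None:
    """Accuracy-vs-exclusion-threshold curves, one line per label."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, curve in curves.items():
        ax.plot(curve["threshold"], curve["r_horizontal"], "o-", label=label)
    ax.set_xlabel("exclusion threshold (deg)")
    ax.set_ylabel("horizontal accuracy (r)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
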