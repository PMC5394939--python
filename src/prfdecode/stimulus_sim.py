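"""Random-walk stimulus simulation and frame-to-volume alignment.

The stimulus is a disk (a projected sphere) whose center performs a
momentum-driven random walk inside a square field centered on fixation.
Per frame the center moves a fixed distance ``c`` along a unit direction
vector; the direction receives isotropic Gaussian perturbations and is
renormalized, and hitting a field boundary reflects the corresponding
direction component before the step is taken.  Frame-level positions are
then down-sampled to one position per fMRI volume according to the run
schedule (rest periods drop out) with a fixed hemodynamic shift.

All spatial quantities are in degrees of visual angle; x increases
rightward and y upward, with the origin at fixation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryConfig",
    "Trajectory",
    "RunSchedule",
    "StimulusSpec",
    "VolumeSeries",
    "simulate_trajectory",
    "render_stimulus",
    "pixel_grid",
    "frames_to_volumes",
    "schedule_duration",
]


@dataclass(frozen=True)
class TrajectoryConfig:
    """Parameters of the stimulus-center random walk.

    speed_c
        Step length per frame, degrees.  Each step has exactly this
        length because the direction vector is kept at unit norm.
    sigma_stim
        SD of the isotropic Gaussian direction perturbation
        (dimensionless; added to the unit direction before
        renormalization).
    frame_rate
        Display frame rate in Hz.
    center_field_half_width
        Half-width of the square field the *center* may occupy; the
        stimulus disk itself spans this plus its radius on each side.
    stimulus_radius
        Disk radius, degrees.
    seed
        Seed for the direction-noise stream and the initial direction.
    initial_position, initial_direction
        Optional starting state; by default the walk starts at fixation
        with a uniformly random initial direction.
    """

    speed_c: float = 0.008
    sigma_stim: float = 0.1
    frame_rate: float = 60.0
    center_field_half_width: float = 3.0
    stimulus_radius: float = 0.8
    seed: int = 0
    initial_position: tuple[float, float] = (0.0, 0.0)
    initial_direction: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        bad = []
        if not self.speed_c > 0:
            bad.append("speed_c")
        if self.sigma_stim < 0:
            bad.append("sigma_stim")
        if not self.frame_rate > 0:
            bad.append("frame_rate")
        if not self.center_field_half_width > 0:
            bad.append("center_field_half_width")
        if not self.stimulus_radius > 0:
            bad.append("stimulus_radius")
        if bad:
            raise ValueError(f"invalid TrajectoryConfig fields: {bad}")


@dataclass
class Trajectory:
    """Frame-level stimulus-center positions and unit direction vectors."""

    positions: np.ndarray  # (n_frames, 2), degrees
    directions: np.ndarray  # (n_frames, 2), unit vectors

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "sx_deg": self.positions[:, 0],
                "sy_deg": self.positions[:, 1],
                "px": self.directions[:, 0],
                "py": self.directions[:, 1],
            }
        )


@dataclass(frozen=True)
class RunSchedule:
    """Timing of one scanning run, in seconds.

    A run is an initial rest, ``n_blocks`` stimulus blocks separated by
    inter-block rests, and a final rest.  Volumes are sampled every
    ``tr_s`` seconds; measured activity is paired with the stimulus
    ``hemodynamic_shift_s`` earlier; the first ``discard_initial_s``
    of acquisition (inside the initial rest) are discarded.
    """

    initial_rest_s: float = 32.0
    block_duration_s: float = 240.0
    n_blocks: int = 4
    inter_block_rest_s: float = 12.0
    final_rest_s: float = 12.0
    tr_s: float = 2.0
    hemodynamic_shift_s: float = 4.0
    discard_initial_s: float = 8.0

    def __post_init__(self) -> None:
        bad = [
            name
            for name in (
                "initial_rest_s",
                "block_duration_s",
                "inter_block_rest_s",
                "final_rest_s",
                "tr_s",
                "hemodynamic_shift_s",
                "discard_initial_s",
            )
            if getattr(self, name) < 0
        ]
        if self.n_blocks < 1:
            bad.append("n_blocks")
        if bad:
            raise ValueError(f"invalid RunSchedule fields: {bad}")
        if self.tr_s > 0 and abs(self.block_duration_s / self.tr_s - round(self.block_duration_s / self.tr_s)) > 1e-9:
            raise ValueError("block_duration_s must be divisible by tr_s")

    @property
    def volumes_per_block(self) -> int:
        return int(round(self.block_duration_s / self.tr_s))

    @property
    def stimulus_volumes_per_run(self) -> int:
        return self.n_blocks * self.volumes_per_block


@dataclass(frozen=True)
class StimulusSpec:
    """Rasterization of the binary stimulus indicator.

    ``pixel_size`` is the render-grid resolution (degrees); the grid is
    symmetric about fixation and covers ±``render_extent``.  The default
    extent covers the full span field the disk can reach
    (center field half-width 3.0° + radius 0.8°).
    """

    pixel_size: float = 0.1
    render_extent: float = 3.8

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not self.render_extent > 0:
            raise ValueError("render_extent must be positive")

    @property
    def n_pixels(self) -> int:
        return int(round(2 * self.render_extent / self.pixel_size))

    @property
    def pixel_centers(self) -> np.ndarray:
        n = self.n_pixels
        return (np.arange(n) + 0.5) * self.pixel_size - self.render_extent

    @property
    def pixel_area(self) -> float:
        return self.pixel_size**2


@dataclass
class VolumeSeries:
    """One stimulus position per fMRI volume, with run labels."""

    positions: np.ndarray  # (n_volumes, 2), degrees
    run_ids: np.ndarray  # (n_volumes,), int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.run_ids = np.asarray(self.run_ids)
        if len(self.positions) != len(self.run_ids):
            raise ValueError("positions and run_ids must have equal length")

    @property
    def n_volumes(self) -> int:
        return self.positions.shape[0]

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run_ids)

    def subset(self, mask: np.ndarray) -> "VolumeSeries":
        return VolumeSeries(self.positions[mask], self.run_ids[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "volume": np.arange(self.n_volumes),
                "run": self.run_ids,
                "sx_deg": self.positions[:, 0],
                "sy_deg": self.positions[:, 1],
            }
        )


def simulate_trajectory(config: TrajectoryConfig, n_frames: int) -> Trajectory:
    """Simulate the stimulus-center random walk for ``n_frames`` frames.

    Per frame: the provisional step ``s + c*p`` is tested against the
    center field independently per axis; any component of ``p`` whose
    axis would leave the field is negated (corner hits negate both);
    the step is then taken with the possibly-reflected ``p``; finally
    ``p`` receives an isotropic Gaussian perturbation with SD
    ``sigma_stim`` per component and is renormalized.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(config.seed)
    hw = config.center_field_half_width
    c = config.speed_c

    s = np.asarray(config.initial_position, dtype=float)
    if np.any(np.abs(s) > hw):
        raise ValueError("initial_position outside the center field")
    if config.initial_direction is None:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        p = np.array([np.cos(theta), np.sin(theta)])
    else:
        p = np.asarray(config.initial_direction, dtype=float)
        p = p / np.linalg.norm(p)

    positions = np.empty((n_frames, 2))
    directions = np.empty((n_frames, 2))
    positions[0] = s
    directions[0] = p
    # noise drawn up-front so the stream is independent of reflections
    eps = rng.normal(0.0, config.sigma_stim, size=(n_frames, 2))
    for t in range(1, n_frames):
        prov = s + c * p
        if abs(prov[0]) > hw:
            p[0] = -p[0]
        if abs(prov[1]) > hw:
            p[1] = -p[1]
        s = s + c * p
        p = p + eps[t]
        p /= np.linalg.norm(p)
        positions[t] = s
        directions[t] = p
    return Trajectory(positions=positions, directions=directions)


def pixel_grid(spec: StimulusSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (X, Y) pixel-center coordinate arrays, y-row-major.

    Row index increases with y, column index with x.
    """
    coords = spec.pixel_centers
    return np.meshgrid(coords, coords, indexing="xy")


def render_stimulus(
    position: tuple[float, float], spec: StimulusSpec, radius: float
) -> np.ndarray:
    """Rasterize the binary disk indicator at ``position``.

    A pixel is 1 iff its center lies strictly within ``radius`` of the
    disk center.  Positions outside the rendered field produce a clipped
    (possibly empty) disk.
    """
    sx, sy = position
    if not (np.isfinite(sx) and np.isfinite(sy)):
        raise ValueError("position must be finite")
    X, Y = pixel_grid(spec)
    return (((X - sx) ** 2 + (Y - sy) ** 2) < radius**2).astype(np.uint8)


def schedule_duration(schedule: RunSchedule) -> float:
    """Total duration of one run in seconds."""
    return (
        schedule.initial_rest_s
        + schedule.n_blocks * schedule.block_duration_s
        + (schedule.n_blocks - 1) * schedule.inter_block_rest_s
        + schedule.final_rest_s
    )


def frames_to_volumes(
    trajectory: Trajectory, schedule: RunSchedule, n_runs: int, frame_rate: float = 60.0
) -> VolumeSeries:
    """Down-sample frame positions to one position per stimulus volume.

    The trajectory is taken to run continuously through the stimulus
    blocks of all runs (rest periods freeze it and contribute no
    frames).  Each TR window maps to the frame at its midpoint; rest
    volumes are excluded.  The pairing of a volume with activity
    measured ``hemodynamic_shift_s`` later is a bookkeeping convention
    for measured data and does not alter the positions.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    fpt = int(round(schedule.tr_s * frame_rate))
    fpb = int(round(schedule.block_duration_s * frame_rate))
    vpb = schedule.volumes_per_block
    needed = n_runs * schedule.n_blocks * fpb
    if trajectory.n_frames < needed:
        raise ValueError(
            f"trajectory has {trajectory.n_frames} frames; "
            f"{needed} required for {n_runs} run(s)"
        )
    positions = []
    run_ids = []
    block = 0
    for run in range(n_runs):
        for _ in range(schedule.n_blocks):
            base = block * fpb
            idx = base + np.arange(vpb) * fpt + fpt // 2
            positions.append(trajectory.positions[idx])
            run_ids.append(np.full(vpb, run))
            block += 1
    return VolumeSeries(
        positions=np.concatenate(positions), run_ids=np.concatenate(run_ids)
    )
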