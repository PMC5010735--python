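"""Core domain containers.

Units are fixed package-wide: time in minutes, positions in micrometres,
angles in degrees in ``(-180, 180]`` unless a field says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import ValidationError

RUN = "run"
TUMBLE = "tumble"


@dataclass
class Trajectory:
    """Time-stamped 3D track of one cell.

    Parameters
    ----------
    cell_id
        Identifier of the tracked cell.
    times
        Strictly increasing time stamps in minutes.
    positions
        ``(n, 3)`` array of x, y, z coordinates in micrometres.  For 2D
        (e.g. simulated) data z is identically zero.
    condition
        Experimental condition label, e.g. ``"control"``, ``"ezrin_MO"``.
    """

    cell_id: str
    times: np.ndarray
    positions: np.ndarray
    condition: str = "control"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError(
                f"positions must be (n, 3); got {self.positions.shape}"
            )
        if len(self.times) != len(self.positions):
            raise ValidationError("times and positions length mismatch")
        if len(self.times) < 2:
            raise ValidationError("a trajectory needs at least 2 points")
        if not np.all(np.isfinite(self.times)) or not np.all(
            np.isfinite(self.positions)
        ):
            raise ValidationError("non-finite time or coordinate")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"times must be strictly increasing (cell {self.cell_id})"
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def sampling_interval(self) -> float:
        """Median frame-to-frame interval in minutes."""
        return float(np.median(np.diff(self.times)))

    def is_uniformly_sampled(self, rtol: float = 0.01) -> bool:
        dt = np.diff(self.times)
        return bool(np.all(np.abs(dt - dt.mean()) <= rtol * dt.mean()))

    @property
    def displacements(self) -> np.ndarray:
        """``(n-1, 3)`` frame-to-frame displacement vectors, micrometres."""
        return np.diff(self.positions, axis=0)

    @property
    def path_length(self) -> float:
        return float(np.linalg.norm(self.displacements, axis=1).sum())

    @property
    def net_displacement(self) -> float:
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))

    @property
    def persistence(self) -> float:
        """Directional persistence: net displacement over path length, in [0, 1]."""
        L = self.path_length
        return float(self.net_displacement / L) if L > 0 else 0.0


@dataclass
class ProtrusionEventRecord:
    """One detected protrusion linked to a cell.

    ``angle`` is measured relative to the local migration direction,
    degrees in ``(-180, 180]``; ``weight`` is the total Lifeact intensity
    for actin-rich protrusions and 1 for blebs.
    """

    cell_id: str
    time: float
    kind: str  # bleb | actin_rich | unclassified
    angle: float
    weight: float = 1.0
    projected_area: float | None = None
    cell_projected_area: float | None = None

    KINDS = ("bleb", "actin_rich", "unclassified")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown protrusion kind {self.kind!r}")
        if self.weight < 0:
            raise ValidationError(f"negative weight {self.weight}")
        if not (-180.0 < self.angle <= 180.0):
            raise ValidationError(f"angle {self.angle} outside (-180, 180]")
        if self.kind == "actin_rich" and self.weight == 0:
            raise ValidationError("actin_rich protrusion must carry weight > 0")


@dataclass
class PhaseSegment:
    """Contiguous run or tumble segment, half-open in time: [t_start, t_end)."""

    phase: str
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class PhaseAnnotation:
    """Per-timepoint run/tumble labels plus the contiguous segment list.

    ``labels[k]`` is the phase of the motion starting at timepoint ``k``
    (the last timepoint inherits the preceding label and carries no
    interval of its own).  ``segments`` tile ``[t_0, t_{n-1}]``, so
    segment durations sum exactly to the track duration.
    ``exact_segments``, when present, holds the generator's
    continuous-time ground-truth switch intervals.
    """

    cell_id: str
    times: np.ndarray
    labels: np.ndarray  # array of "run"/"tumble", same length as times
    segments: list[PhaseSegment] = field(default_factory=list)
    exact_segments: list[PhaseSegment] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.times) != len(self.labels):
            raise ValidationError("times and labels length mismatch")
        bad = set(self.labels) - {RUN, TUMBLE}
        if bad:
            raise ValidationError(f"unknown phase labels: {bad}")
        if not self.segments:
            self.segments = segments_from_labels(self.times, self.labels)
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.isclose(a.t_end, b.t_start):
                raise ValidationError("segments do not tile the trajectory")
            if a.duration <= 0:
                raise ValidationError("non-positive segment duration")

    def durations(self, phase: str) -> np.ndarray:
        return np.array(
            [s.duration for s in self.segments if s.phase == phase], dtype=float
        )

    def total_time(self, phase: str) -> float:
        return float(self.durations(phase).sum())


def segments_from_labels(times: np.ndarray, labels: Sequence[str]) -> list[PhaseSegment]:
    """Build the tiling segment list from per-timepoint labels.

    ``labels[k]`` covers the interval ``[t_k, t_{k+1})``; the final
    timepoint carries no interval of its own (it inherits the preceding
    label), so segment durations sum exactly to the track duration.
    """
    times = np.asarray(times, dtype=float)
    labels = np.asarray(labels, dtype=object)
    segs: list[PhaseSegment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segs.append(
                PhaseSegment(
                    phase=str(labels[start]),
                    t_start=times[start],
                    t_end=times[-1] if i == len(labels) else times[i],
                )
            )
            start = i
    return segs


@dataclass
class ASSeries:
    """Alignment index A and scaled speed S per displacement frame.

    ``A[i]`` is the mean cosine between displacement ``i`` and its
    neighbours within ``window`` frames; ``S[i]`` is the instantaneous
    speed scaled by the trajectory's mean speed.  ``zero_flag`` marks
    frames with zero displacement where A is undefined and carried as 0.
    """

    cell_id: str
    times: np.ndarray
    A: np.ndarray
    S: np.ndarray
    zero_flag: np.ndarray
    window: int

    def __post_init__(self) -> None:
        if np.any(self.A[~self.zero_flag] < -1 - 1e-9) or np.any(
            self.A[~self.zero_flag] > 1 + 1e-9
        ):
            raise ValidationError("alignment index outside [-1, 1]")
        if np.any(self.S < 0):
            raise ValidationError("scaled speed must be >= 0")


@dataclass
class ASDensity:
    """Estimated 2D probability density P(A, S) with its maximum-line fit.

    ``density[i, j]`` is the probability density at ``(a_grid[i], s_grid[j])``;
    the density integrates to one over the grid.  ``slope``/``intercept``
    define the maximum line S*(A); ``threshold_A`` is the run/tumble
    cut-off abscissa on that line.  ``a_std``/``s_std`` are the pooled
    standard deviations used to standardise coordinates when projecting
    points onto the line.
    """

    a_grid: np.ndarray
    s_grid: np.ndarray
    density: np.ndarray
    a_std: float
    s_std: float
    n_points: int
    bandwidth: float
    slope: float | None = None
    intercept: float | None = None
    threshold_A: float | None = None
    cross_section_a: np.ndarray | None = None
    cross_section: np.ndarray | None = None
    threshold_fallback: bool = False

    @property
    def bin_area(self) -> float:
        da = self.a_grid[1] - self.a_grid[0]
        ds = self.s_grid[1] - self.s_grid[0]
        return float(da * ds)


@dataclass
class PhaseSummary:
    """Per-phase summary statistics of one annotated trajectory (or pool)."""

    tumble_run_time_ratio: float
    mean_run_duration: float
    mean_tumble_duration: float
    run_speed: float
    tumble_speed: float
    speed_ratio: float
    inter_run_angles: np.ndarray
    persistence: float
    n_runs: int
    n_tumbles: int


@dataclass
class SimulationParams:
    """Parameters of the run-and-tumble pursuit model.

    The cell alternates exponentially distributed run (mean ``tau_r``) and
    tumble (mean ``tau_t``) phases while a target moves along +x at
    ``v_target`` from initial distance ``d0``.  At each run start the
    heading is aimed at the current target position with Gaussian angular
    error ``sigma_eps``; during runs the heading fluctuates around that
    mean (Ornstein-Uhlenbeck with relaxation time ``tau_rel`` and
    stationary SD ``sqrt(D_theta * tau_rel)``), while tumbles redraw an
    isotropic heading every integration step.  Speeds are truncated
    Gaussians redrawn each ``dt``.
    """

    tau_r: float = 5.0  # mean run duration, min
    tau_t: float = 3.1  # mean tumble duration, min
    v_run_mean: float = 2.4  # um/min
    v_run_sd: float = 0.8
    v_tumble_mean: float = 2.4  # um/min (generative; observed tumble speed is lower)
    v_tumble_sd: float = 1.0
    D_theta: float = 0.1  # rad^2/min rotational diffusion during runs
    sigma_eps: float = 0.7  # rad, target-detection error SD at run start
    v_target: float = 1.0  # um/min
    d0: float = 300.0  # um
    t_e: float = 90.0  # evaluation time, min
    dt: float = 0.1  # integration step, min
    sample_interval: float = 1.5  # output sampling, min
    n_cells: int = 23
    seed: int = 0
    tau_rel: float = 1.0  # heading OU relaxation time, min
    tumble_rotdiff: bool = False  # rotational-diffusion tumble variant

    def validate(self) -> None:
        positive = [
            ("tau_r", self.tau_r),
            ("tau_t", self.tau_t),
            ("v_run_mean", self.v_run_mean),
            ("v_tumble_mean", self.v_tumble_mean),
            ("v_target", self.v_target),
            ("d0", self.d0),
            ("t_e", self.t_e),
            ("dt", self.dt),
            ("sample_interval", self.sample_interval),
            ("tau_rel", self.tau_rel),
        ]
        for name, v in positive:
            if not v > 0:
                raise ValidationError(f"{name} must be > 0, got {v}")
        for name, v in [
            ("v_run_sd", self.v_run_sd),
            ("v_tumble_sd", self.v_tumble_sd),
            ("D_theta", self.D_theta),
            ("sigma_eps", self.sigma_eps),
        ]:
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.dt > self.sample_interval / 3 + 1e-12:
            raise ValidationError("dt must be <= sample_interval / 3")
        n = self.t_e / self.sample_interval
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("t_e must be a multiple of sample_interval")

    def replace(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


@dataclass
class SweepResult:
    """Read-outs of a run-time sweep: one row per tau_r multiplier."""

    factors: np.ndarray
    mean_distance: np.ndarray  # um, mean over replicates of ensemble means
    dispersion: np.ndarray  # um^2, mean over replicates of var_x + var_y
    n_reps: int
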