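"""Unbiased run/tumble segmentation of cell trajectories.

The pipeline pools an alignment index A (local directional persistence,
in [-1, 1]) and a scaled speed S (instantaneous speed over the
trajectory mean) across an ensemble of tracks, estimates the 2D
probability density P(A, S), fits a line through the per-A density
maxima, locates the density minimum along that line between the run and
tumble modes, and classifies each timepoint by which side of the
perpendicular through that minimum its (A, S) projection falls on.
A short-track classifier based on a 45-degree / 5-frame rule is provided
for high-frame-rate movies where the density approach is not applicable.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, signal

from .exceptions import FitError, ValidationError
from .types import (
    RUN,
    TUMBLE,
    ASDensity,
    ASSeries,
    PhaseAnnotation,
    PhaseSummary,
    Trajectory,
    segments_from_labels,
)

DEFAULT_WINDOW = 2
DEFAULT_A_BINS = 41
DEFAULT_S_BINS = 41
DEFAULT_S_MAX = 3.0
# kernel SD of 2 bins: at ~1.8k pooled points per 23-cell ensemble the
# 41x41 histogram is sparse, and a 1.5-bin kernel leaves mode-sized ripples
# that destabilise the threshold between realisations
DEFAULT_BANDWIDTH = 2.0
# no minimum segment length by default: tumbles at this sampling are often a
# single frame, and merging them away inflates run durations ~2x; pass
# min_segment=2 to suppress single-frame flicker when the data warrant it
DEFAULT_MIN_SEGMENT = 1


def compute_alignment_and_speed(
    traj: Trajectory, window: int = DEFAULT_WINDOW
) -> ASSeries:
    """Per-frame alignment index A and scaled speed S of one trajectory.

    ``A[i]`` is the mean cosine of the angles between displacement ``i``
    and the displacements within ``window`` frames on either side
    (truncated at the track ends); ``S[i]`` is ``|displacement_i| / dt``
    divided by the trajectory's mean instantaneous speed.  Frames with
    zero displacement get ``A = S = 0`` and are flagged.

    Requires uniform sampling (1% tolerance) and at least ``window + 2``
    points.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    if len(traj) < window + 2:
        raise ValidationError(
            f"trajectory {traj.cell_id} too short for window {window}"
        )
    if not traj.is_uniformly_sampled(rtol=0.01):
        raise ValidationError(
            f"trajectory {traj.cell_id} is not uniformly sampled; resample first"
        )
    v = traj.displacements
    n = len(v)
    dt = traj.sampling_interval
    norms = np.linalg.norm(v, axis=1)
    zero = norms == 0
    speeds = norms / dt
    mean_speed = speeds.mean()
    if mean_speed == 0:
        raise ValidationError(f"trajectory {traj.cell_id} does not move")
    # unit vectors; zero-displacement frames contribute nothing
    u = np.zeros_like(v)
    u[~zero] = v[~zero] / norms[~zero, None]
    cosmat_ok = ~zero
    A = np.zeros(n)
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        idx = [k for k in range(lo, hi) if k != i and cosmat_ok[k]]
        if zero[i] or not idx:
            A[i] = 0.0
        else:
            A[i] = float(np.clip(u[idx] @ u[i], -1.0, 1.0).mean())
    S = speeds / mean_speed
    S[zero] = 0.0
    return ASSeries(
        cell_id=traj.cell_id,
        times=traj.times[:-1].copy(),
        A=A,
        S=S,
        zero_flag=zero,
        window=window,
    )


def estimate_density(
    series: list[ASSeries] | ASSeries,
    a_bins: int = DEFAULT_A_BINS,
    s_bins: int = DEFAULT_S_BINS,
    bandwidth: float = DEFAULT_BANDWIDTH,
    s_max: float = DEFAULT_S_MAX,
) -> ASDensity:
    """Estimate P(A, S) pooled over an ensemble of A/S series.

    A 2D histogram on a fixed grid (A in [-1, 1], S in [0, s_max]) is
    smoothed with a separable Gaussian kernel of SD ``bandwidth`` bins
    and renormalised to unit mass.  S values beyond ``s_max`` are clipped
    into the top bin.
    """
    if isinstance(series, ASSeries):
        series = [series]
    if not series:
        raise ValidationError("no A/S series given")
    A = np.concatenate([s.A for s in series])
    S = np.concatenate([s.S for s in series])
    if A.size == 0:
        raise ValidationError("empty A/S input")
    if np.allclose(A, A[0]) and np.allclose(S, S[0]):
        raise ValidationError("degenerate input: all (A, S) points identical")
    if A.size < 500:
        warnings.warn(
            f"only {A.size} pooled (A, S) points; density may be unreliable",
            stacklevel=2,
        )
    a_edges = np.linspace(-1.0, 1.0, a_bins + 1)
    s_edges = np.linspace(0.0, s_max, s_bins + 1)
    Sc = np.clip(S, 0.0, s_max - 1e-9)
    Ac = np.clip(A, -1.0, 1.0 - 1e-9)
    H, _, _ = np.histogram2d(Ac, Sc, bins=[a_edges, s_edges])
    if bandwidth > 0:
        H = ndimage.gaussian_filter(H, sigma=bandwidth, mode="constant")
    area = (a_edges[1] - a_edges[0]) * (s_edges[1] - s_edges[0])
    H = H / (H.sum() * area)
    return ASDensity(
        a_grid=0.5 * (a_edges[:-1] + a_edges[1:]),
        s_grid=0.5 * (s_edges[:-1] + s_edges[1:]),
        density=H,
        a_std=float(np.std(A)),
        s_std=float(np.std(S)),
        n_points=int(A.size),
        bandwidth=bandwidth,
    )


def fit_maximum_line(d: ASDensity, mass_floor: float = 0.05) -> tuple[float, float]:
    """Least-squares line S*(A) through the per-A density maxima.

    Only A columns whose peak exceeds ``mass_floor`` of the global peak
    contribute.  Returns (slope, intercept) and stores them on ``d``.
    """
    peak_s_idx = d.density.argmax(axis=1)
    peaks = d.density[np.arange(len(d.a_grid)), peak_s_idx]
    usable = peaks >= mass_floor * d.density.max()
    if usable.sum() < 2:
        raise FitError("fewer than 2 usable A columns for the maximum-line fit")
    if usable.sum() < 5:
        warnings.warn(
            f"only {int(usable.sum())} A columns above the mass floor", stacklevel=2
        )
    x = d.a_grid[usable]
    y = d.s_grid[peak_s_idx[usable]]
    slope, intercept = np.polyfit(x, y, 1)
    d.slope, d.intercept = float(slope), float(intercept)
    return d.slope, d.intercept


def _profile_along_line(d: ASDensity) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear sample of the density along the fitted maximum line."""
    a = d.a_grid
    s = d.slope * a + d.intercept
    inside = (s >= d.s_grid[0]) & (s <= d.s_grid[-1])
    a, s = a[inside], s[inside]
    # map to fractional grid indices for bilinear interpolation
    ai = np.interp(a, d.a_grid, np.arange(len(d.a_grid)))
    si = np.interp(s, d.s_grid, np.arange(len(d.s_grid)))
    prof = ndimage.map_coordinates(d.density, [ai, si], order=1, mode="nearest")
    return a, prof


def find_threshold(d: ASDensity, prominence_frac: float = 0.15) -> float:
    """Locate the run/tumble threshold along the maximum line.

    The threshold abscissa is the local minimum of the 1D cross-section
    of P(A, S) along the maximum line, between the global maximum and the
    nearest distinct local maximum.  A secondary mode only counts if its
    prominence reaches ``prominence_frac`` of the profile maximum; on
    profiles without convincing bimodality the knee of the shoulder
    (maximum deviation below the mode-to-tail chord) is used instead and
    flagged as a fallback.
    """
    if d.slope is None:
        raise FitError("fit_maximum_line must be called before find_threshold")
    a, prof = _profile_along_line(d)
    if len(a) < 5:
        raise FitError("cross-section along the maximum line is too short")
    d.cross_section_a, d.cross_section = a, prof
    # zero-pad so a mode abutting either end of the profile keeps its full
    # prominence (the run mode typically sits against A = 1)
    padded = np.concatenate([[0.0], prof, [0.0]])
    peaks, _ = signal.find_peaks(padded, prominence=prominence_frac * prof.max())
    peaks = np.sort(peaks - 1)
    g = int(peaks[np.argmax(prof[peaks])]) if len(peaks) else int(np.argmax(prof))
    others = [p for p in peaks if p != g]
    if others:
        nearest = min(others, key=lambda p: abs(a[p] - a[g]))
        lo, hi = sorted((g, int(nearest)))
        valley = lo + int(np.argmin(prof[lo : hi + 1]))
        d.threshold_fallback = False
        d.threshold_A = float(a[valley])
    else:
        # unimodal: knee of the shoulder on the side of the mode with the
        # longer tail (where the second phase's mass hides), located as the
        # point of maximum deviation from the chord mode -> tail end
        left_tail = g
        right_tail = len(prof) - 1 - g
        if right_tail >= left_tail:
            idx = np.arange(g, len(prof))
        else:
            idx = np.arange(g, -1, -1)
        y = prof[idx]
        x = np.arange(len(y), dtype=float)
        chord = y[0] + (y[-1] - y[0]) * x / max(len(y) - 1, 1)
        knee = int(np.argmax(chord - y))
        d.threshold_fallback = True
        d.threshold_A = float(a[idx[knee]])
        warnings.warn(
            "cross-section is unimodal; threshold set at the curvature knee "
            "(fallback)",
            stacklevel=2,
        )
    return d.threshold_A


def project_on_maximum_line(d: ASDensity, A: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Signed arclength coordinate of (A, S) points along the maximum line.

    A and S are standardised to unit variance (pooled SDs stored on the
    density) so the orthogonal projection is well defined on mixed units;
    the coordinate increases with A and is zero at the threshold point.
    """
    if d.threshold_A is None:
        raise FitError("threshold not set; call find_threshold first")
    sa, ss = max(d.a_std, 1e-12), max(d.s_std, 1e-12)
    direction = np.array([1.0 / sa, d.slope / ss])
    direction /= np.linalg.norm(direction)
    thr = np.array(
        [d.threshold_A / sa, (d.slope * d.threshold_A + d.intercept) / ss]
    )
    pts = np.stack([np.asarray(A) / sa, np.asarray(S) / ss], axis=1)
    return (pts - thr) @ direction


def _merge_short_segments(labels: np.ndarray, min_segment: int) -> np.ndarray:
    """Merge segments shorter than ``min_segment`` frames into a neighbour.

    The shorter offender is absorbed by the longer adjacent segment
    (tie: the preceding one), repeatedly until no offender remains.
    """
    labels = labels.copy()
    while True:
        runs = []  # (start, length)
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                runs.append((start, i - start))
                start = i
        if len(runs) <= 1:
            return labels
        offenders = [k for k, (_, ln) in enumerate(runs) if ln < min_segment]
        if not offenders:
            return labels
        k = min(offenders, key=lambda k: runs[k][1])
        s, ln = runs[k]
        prev_len = runs[k - 1][1] if k > 0 else -1
        next_len = runs[k + 1][1] if k < len(runs) - 1 else -1
        if prev_len >= next_len:
            labels[s : s + ln] = labels[s - 1]
        else:
            labels[s : s + ln] = labels[s + ln]
    return labels


def classify_phases(
    traj: Trajectory,
    d: ASDensity,
    window: int = DEFAULT_WINDOW,
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> PhaseAnnotation:
    """Label every timepoint of ``traj`` as run or tumble.

    Each displacement frame's (A, S) point is projected onto the maximum
    line (standardised coordinates); frames beyond the threshold point
    are runs.  Segments shorter than ``min_segment`` frames are merged
    into their longer neighbour, and the final timepoint inherits the
    label of the last displacement.
    """
    series = compute_alignment_and_speed(traj, window=window)
    coord = project_on_maximum_line(d, series.A, series.S)
    frame_labels = np.where(coord > 0, RUN, TUMBLE).astype(object)
    frame_labels = _merge_short_segments(frame_labels, min_segment)
    labels = np.append(frame_labels, frame_labels[-1])
    return PhaseAnnotation(
        cell_id=traj.cell_id,
        times=traj.times.copy(),
        labels=labels,
        meta={
            "window": window,
            "min_segment": min_segment,
            "threshold_A": d.threshold_A,
            "slope": d.slope,
            "intercept": d.intercept,
            "threshold_fallback": d.threshold_fallback,
        },
    )


def classify_phases_short(
    traj: Trajectory,
    angle_threshold: float = 45.0,
    persist_frames: int = 5,
) -> PhaseAnnotation:
    """Run/tumble segmentation for short high-frame-rate tracks.

    A run continues while the direction of motion stays within
    ``angle_threshold`` degrees of the run's initial direction, or while
    a larger deviation lasts fewer than ``persist_frames`` frames.  A
    deviation that persists ``persist_frames`` or more opens a tumble,
    which ends when ``persist_frames`` consecutive frames agree with a
    stable new direction.
    """
    if len(traj) < persist_frames + 1:
        raise ValidationError("trajectory too short for the persistence rule")
    v = traj.displacements
    n = len(v)
    norms = np.linalg.norm(v, axis=1)
    u = np.zeros_like(v)
    ok = norms > 0
    u[ok] = v[ok] / norms[ok, None]
    cos_thr = np.cos(np.radians(angle_threshold))

    def within(i: int, ref: np.ndarray) -> bool:
        return ok[i] and float(u[i] @ ref) >= cos_thr

    labels = np.empty(n, dtype=object)
    i = 0
    state = RUN
    ref = u[0]
    while i < n:
        if state == RUN:
            if within(i, ref):
                labels[i] = RUN
                i += 1
                continue
            # count how long the deviation persists
            j = i
            while j < n and not within(j, ref):
                j += 1
            if j - i >= persist_frames:
                # deviation persists: the first persist_frames deviating
                # frames are the tumble's evidence window; a new run can
                # begin at the earliest after them
                state = TUMBLE
                labels[i : i + persist_frames] = TUMBLE
                i = i + persist_frames
            else:
                labels[i:j] = RUN  # transient deviation stays part of the run
                i = j
        else:
            # look for a stable new direction starting at i
            started = False
            for k in range(i, n):
                if not ok[k]:
                    continue
                horizon = min(n, k + persist_frames)
                if all(within(m, u[k]) for m in range(k, horizon)):
                    labels[i:k] = TUMBLE
                    ref = u[k]
                    state = RUN
                    i = k
                    started = True
                    break
            if not started:
                labels[i:] = TUMBLE
                i = n
    full = np.append(labels, labels[-1])
    return PhaseAnnotation(
        cell_id=traj.cell_id,
        times=traj.times.copy(),
        labels=full,
        meta={"angle_threshold": angle_threshold, "persist_frames": persist_frames},
    )


def phase_statistics(
    traj: Trajectory,
    ann: PhaseAnnotation,
    sampling_interval: float | None = None,
) -> PhaseSummary:
    """Per-phase summary statistics of one annotated trajectory.

    Instantaneous speeds are pooled by the phase of each displacement
    frame; ``speed_ratio`` is mean run speed over mean tumble speed;
    inter-run angles are measured in 3D between the net displacements of
    consecutive run segments.
    """
    if len(ann.times) != len(traj.times) or not np.allclose(ann.times, traj.times):
        raise ValidationError("annotation does not match trajectory times")
    dt = sampling_interval or traj.sampling_interval
    v = traj.displacements
    speeds = np.linalg.norm(v, axis=1) / dt
    frame_phase = ann.labels[:-1]
    run_speeds = speeds[frame_phase == RUN]
    tumble_speeds = speeds[frame_phase == TUMBLE]
    run_speed = float(run_speeds.mean()) if run_speeds.size else np.nan
    tumble_speed = float(tumble_speeds.mean()) if tumble_speeds.size else np.nan
    speed_ratio = (
        run_speed / tumble_speed
        if tumble_speeds.size and tumble_speed > 0
        else np.inf
    )
    run_durs = ann.durations(RUN)
    tum_durs = ann.durations(TUMBLE)
    total_run = run_durs.sum()
    ratio = float(tum_durs.sum() / total_run) if total_run > 0 else np.inf

    # net displacement of each run segment, in trajectory order
    time_to_idx = {round(t, 9): i for i, t in enumerate(traj.times)}
    net_vecs = []
    n_pts = len(traj)
    for seg in ann.segments:
        if seg.phase != RUN:
            continue
        i0 = time_to_idx[round(seg.t_start, 9)]
        # segment covers frames i0 .. i1; motion extends to point i1 + 1
        n_frames = int(round(seg.duration / dt))
        i_end = min(i0 + n_frames, n_pts - 1)
        net_vecs.append(traj.positions[i_end] - traj.positions[i0])
    angles = []
    for w1, w2 in zip(net_vecs, net_vecs[1:]):
        n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
        if n1 > 0 and n2 > 0:
            c = np.clip(w1 @ w2 / (n1 * n2), -1.0, 1.0)
            angles.append(np.degrees(np.arccos(c)))
    return PhaseSummary(
        tumble_run_time_ratio=ratio,
        mean_run_duration=float(run_durs.mean()) if run_durs.size else np.nan,
        mean_tumble_duration=float(tum_durs.mean()) if tum_durs.size else np.nan,
        run_speed=run_speed,
        tumble_speed=tumble_speed,
        speed_ratio=float(speed_ratio),
        inter_run_angles=np.array(angles, dtype=float),
        persistence=traj.persistence,
        n_runs=int(run_durs.size),
        n_tumbles=int(tum_durs.size),
    )


def fit_exponential_durations(
    durations,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float], float]:
    """Maximum-likelihood exponential fit to phase durations.

    Returns (mean, bootstrap 95% CI of the mean, SD/mean diagnostic).
    For an exponential sample SD/mean is close to 1.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ValidationError("no durations given")
    if np.any(durations <= 0):
        raise ValidationError("durations must be positive")
    if durations.size < 5:
        warnings.warn("fewer than 5 durations; fit is unreliable", stacklevel=2)
    mean = float(durations.mean())
    rng = np.random.default_rng(seed)
    boots = rng.choice(durations, size=(n_boot, durations.size), replace=True).mean(
        axis=1
    )
    ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    cv = float(durations.std(ddof=1) / mean) if durations.size > 1 else 0.0
    return mean, ci, cv


def segment_ensemble(
    trajs: list[Trajectory],
    window: int = DEFAULT_WINDOW,
    a_bins: int = DEFAULT_A_BINS,
    s_bins: int = DEFAULT_S_BINS,
    bandwidth: float = DEFAULT_BANDWIDTH,
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> tuple[ASDensity, list[PhaseAnnotation]]:
    """Full pipeline: pooled density, maximum line, threshold, labels."""
    series = [compute_alignment_and_speed(t, window=window) for t in trajs]
    dens = estimate_density(series, a_bins=a_bins, s_bins=s_bins, bandwidth=bandwidth)
    fit_maximum_line(dens)
    find_threshold(dens)
    anns = [classify_phases(t, dens, window=window, min_segment=min_segment) for t in trajs]
    return dens, anns


def label_agreement(truth: PhaseAnnotation, pred: PhaseAnnotation) -> float:
    """Fraction of timepoints where two annotations agree."""
    if len(truth.labels) != len(pred.labels):
        raise ValidationError("annotations have different lengths")
    return float(np.mean(truth.labels == pred.labels))


def ensemble_summary(
    trajs: list[Trajectory], anns: list[PhaseAnnotation], sampling_interval=None
) -> dict:
    """Pool per-cell phase statistics across an ensemble.

    Durations, speeds and inter-run angles are pooled over segments and
    frames; tumble-to-run time ratio and persistence are averaged per
    cell (cells with no run time are excluded from the ratio).
    """
    summaries = [
        phase_statistics(t, a, sampling_interval) for t, a in zip(trajs, anns)
    ]
    run_durs = np.concatenate([a.durations(RUN) for a in anns])
    tum_durs = np.concatenate([a.durations(TUMBLE) for a in anns])
    ratios = np.array(
        [s.tumble_run_time_ratio for s in summaries if np.isfinite(s.tumble_run_time_ratio)]
    )
    angles = np.concatenate([s.inter_run_angles for s in summaries])
    v_run = np.array([s.run_speed for s in summaries if np.isfinite(s.run_speed)])
    v_tum = np.array(
        [s.tumble_speed for s in summaries if np.isfinite(s.tumble_speed)]
    )
    dt = sampling_interval or trajs[0].sampling_interval
    pooled_run, pooled_tum = [], []
    for t, a in zip(trajs, anns):
        sp = np.linalg.norm(t.displacements, axis=1) / dt
        fp = a.labels[:-1]
        pooled_run.append(sp[fp == RUN])
        pooled_tum.append(sp[fp == TUMBLE])
    pooled_run = np.concatenate(pooled_run)
    pooled_tum = np.concatenate(pooled_tum)
    return {
        "mean_run_duration": float(run_durs.mean()) if run_durs.size else np.nan,
        "mean_tumble_duration": float(tum_durs.mean()) if tum_durs.size else np.nan,
        "tumble_run_time_ratio": float(ratios.mean()) if ratios.size else np.nan,
        "speed_ratio": float(pooled_run.mean() / pooled_tum.mean())
        if pooled_tum.size and pooled_tum.mean() > 0
        else np.nan,
        "run_speed": float(pooled_run.mean()) if pooled_run.size else np.nan,
        "tumble_speed": float(pooled_tum.mean()) if pooled_tum.size else np.nan,
        "mean_inter_run_angle": float(angles.mean()) if angles.size else np.nan,
        "persistence": float(np.mean([s.persistence for s in summaries])),
        "n_runs": int(run_durs.size),
        "n_tumbles": int(tum_durs.size),
    }
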