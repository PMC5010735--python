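"""Calibration of the run-and-tumble model against track statistics.

Simulated ensembles are segmented with exactly the same A/S pipeline
that is applied to experimental tracks, and the generative parameters
are searched so the *segmented* summary statistics match target values.
The printed statistics of real data are read-outs of the segmentation,
not generative parameters, so this closed loop is the only meaningful
way to parameterise the model.

The objective is a weighted sum of squared relative errors; the search
is a Latin-hypercube screen followed by coordinate-wise refinement,
using common random numbers across evaluations so the Monte-Carlo noise
does not swamp the comparison between parameter points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from . import segmentation as seg
from .exceptions import ValidationError
from .model import simulate_ensemble
from .types import SimulationParams

#: statistics the objective can match, in the order residuals are reported
STAT_NAMES = (
    "mean_run_duration",
    "mean_tumble_duration",
    "tumble_run_time_ratio",
    "speed_ratio",
    "mean_inter_run_angle",
    "persistence",
    "run_speed",
)


@dataclass
class CalibrationTargets:
    """Target segmented statistics with per-statistic weights.

    Statistics with weight 0 (or value ``None``) are ignored.  Units:
    durations in minutes, angle in degrees, speeds in um/min; the ratio
    and persistence are dimensionless.
    """

    mean_run_duration: float | None = None
    mean_tumble_duration: float | None = None
    tumble_run_time_ratio: float | None = None
    speed_ratio: float | None = None
    mean_inter_run_angle: float | None = None
    persistence: float | None = None
    run_speed: float | None = None
    weights: dict = field(default_factory=dict)

    def active(self) -> list[tuple[str, float, float]]:
        """(name, target, weight) triples with nonzero weight."""
        out = []
        for name in STAT_NAMES:
            tgt = getattr(self, name)
            if tgt is None:
                continue
            w = float(self.weights.get(name, 1.0))
            if w <= 0:
                continue
            if tgt <= 0:
                raise ValidationError(f"target {name} must be positive")
            out.append((name, float(tgt), w))
        if not out:
            raise ValidationError("no active calibration targets")
        return out


@dataclass
class CalibrationResult:
    best_params: SimulationParams
    objective_value: float
    residuals: dict
    trace: list
    converged: bool
    measured: dict = field(default_factory=dict)


def measure_statistics(
    params: SimulationParams,
    n_cells: int | None = None,
    seed: int | None = None,
    total_time: float = 120.0,
) -> dict:
    """Simulate an ensemble, segment it blind, and pool the statistics."""
    p = params if n_cells is None else params.replace(n_cells=n_cells)
    trajs, _ = simulate_ensemble(p, total_time=total_time, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, anns = seg.segment_ensemble(trajs)
    return seg.ensemble_summary(trajs, anns)


def objective(
    params: SimulationParams,
    targets: CalibrationTargets,
    n_cells: int = 23,
    seed: int = 0,
    total_time: float = 120.0,
    n_ensembles: int = 1,
) -> float:
    """Weighted squared relative error of segmented stats vs targets.

    Deterministic given ``seed`` (common random numbers: the same seed
    should be passed for every parameter point compared).  With
    ``n_ensembles > 1`` the statistics are averaged over that many
    independently seeded ensembles, which damps the threshold-placement
    noise of any single density realisation.
    """
    total = 0.0
    for e in range(n_ensembles):
        stats = measure_statistics(params, n_cells=n_cells, seed=seed + e,
                                   total_time=total_time)
        for name, tgt, w in targets.active():
            sim = stats.get(name, np.nan)
            if not np.isfinite(sim):
                total += w * 25.0  # heavily penalise degenerate segmentations
            else:
                total += w * ((sim - tgt) / tgt) ** 2
    return float(total / n_ensembles)


#: parameters the search may vary, with default box bounds
DEFAULT_BOUNDS = {
    "tau_r": (1.0, 12.0),
    "tau_t": (0.5, 6.0),
    "v_run_mean": (1.0, 5.0),
    "v_run_sd": (0.1, 2.0),
    "v_tumble_mean": (0.5, 6.0),
    "v_tumble_sd": (0.1, 2.5),
    "D_theta": (0.005, 0.6),
    "sigma_eps": (0.1, 1.6),
}


def calibrate(
    targets: CalibrationTargets,
    search_space: dict | None = None,
    budget: int = 200,
    seed: int = 0,
    base_params: SimulationParams | None = None,
    n_cells: int = 23,
    total_time: float = 120.0,
    n_ensembles: int = 3,
) -> CalibrationResult:
    """Fit model parameters so segmented statistics match the targets.

    ``search_space`` maps parameter names to (low, high) bounds; only
    listed parameters are varied, all others stay at ``base_params``.
    Half the budget goes to a Latin-hypercube screen, half to
    coordinate-wise bisection refinement around the best point.  All
    evaluations share one RNG seed (common random numbers).
    """
    if budget < 50:
        raise ValidationError("calibration budget must be >= 50 evaluations")
    space = dict(search_space) if search_space else dict(DEFAULT_BOUNDS)
    for k, (lo, hi) in space.items():
        if not hi > lo:
            raise ValidationError(f"empty bound for {k}: ({lo}, {hi})")
    base = base_params or SimulationParams()
    names = list(space)
    lows = np.array([space[k][0] for k in names])
    highs = np.array([space[k][1] for k in names])
    eval_seed = seed + 1  # CRN stream, distinct from the sampler's

    trace: list[tuple[dict, float]] = []

    def evaluate(x: np.ndarray) -> float:
        kw = dict(zip(names, x))
        p = base.replace(**kw)
        try:
            val = objective(p, targets, n_cells=n_cells, seed=eval_seed,
                            total_time=total_time, n_ensembles=n_ensembles)
        except Exception:
            val = math.inf
        trace.append((kw, val))
        return val

    n_screen = budget // 2
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    X = lows + sampler.random(n_screen) * (highs - lows)
    # include the base point itself in the screen
    X[0] = np.clip(np.array([getattr(base, k) for k in names]), lows, highs)
    vals = np.array([evaluate(x) for x in X])
    best_x = X[int(np.argmin(vals))].copy()
    best_val = float(vals.min())

    # coordinate-wise refinement: shrinking +/- steps around the best point
    n_refine = budget - n_screen
    step = 0.25 * (highs - lows)
    used = 0
    while used < n_refine:
        improved = False
        for j in range(len(names)):
            if used >= n_refine:
                break
            for sign in (+1, -1):
                if used >= n_refine:
                    break
                cand = best_x.copy()
                cand[j] = np.clip(cand[j] + sign * step[j], lows[j], highs[j])
                if np.isclose(cand[j], best_x[j]):
                    continue
                v = evaluate(cand)
                used += 1
                if v < best_val:
                    best_val, best_x = v, cand
                    improved = True
        if not improved:
            step *= 0.5
            if np.all(step < 1e-3 * (highs - lows)):
                break

    best_params = base.replace(**dict(zip(names, best_x)))
    measured = measure_statistics(best_params, n_cells=n_cells, seed=eval_seed,
                                  total_time=total_time)
    residuals = {
        name: (measured.get(name, np.nan) - tgt) / tgt
        for name, tgt, _ in targets.active()
    }
    converged = best_val < 0.05 * sum(w for _, _, w in targets.active())
    if not converged:
        warnings.warn(
            f"calibration not converged (objective {best_val:.3g}); "
            "returning best parameters found",
            stacklevel=2,
        )
    return CalibrationResult(
        best_params=best_params,
        objective_value=best_val,
        residuals=residuals,
        trace=trace,
        converged=converged,
        measured=measured,
    )
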