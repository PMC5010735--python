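"""End-to-end study workflows.

The in vivo statistics of mesendoderm progenitor migration are summary
read-outs of the segmentation pipeline applied to tracked nuclei.  The
workflows here close the loop at desk scale: calibrate the pursuit
model against those read-outs, simulate ensembles of the study's size
(18-23 cells, ~2 h at 1.5-min sampling), segment them blind with the
A/S pipeline, and recover the statistics.
"""

from __future__ import annotations

import numpy as np

from .calibrate import CalibrationResult, CalibrationTargets, calibrate
from .model import simulate_ensemble
from .segmentation import segment_ensemble, ensemble_summary
from .synthetic import SCENARIO_PRESETS
from .types import SimulationParams

#: summary statistics of single control cells migrating in neighbour-free
#: (MZoep) hosts: tumble:run time ratio 0.68 +- 0.38 (n = 23 cells),
#: run/tumble speed ratio ~1.8, inter-run angle 68 +- 37 degrees,
#: segmented mean run/tumble durations ~5 / ~3.1 min
MZOEP_CONTROL_TARGETS = CalibrationTargets(
    mean_run_duration=5.0,
    mean_tumble_duration=3.1,
    tumble_run_time_ratio=0.68,
    speed_ratio=1.8,
    mean_inter_run_angle=68.0,
    weights={
        "speed_ratio": 4.0,
        "tumble_run_time_ratio": 2.0,
        "mean_inter_run_angle": 1.0,
        "mean_run_duration": 0.5,
        "mean_tumble_duration": 0.5,
    },
)

#: the wild-type-host ensemble (n = 18 cells): persistence 0.68 +- 0.13,
#: tumble:run time ratio 0.58 +- 0.34, inter-run angle 56 +- 34 degrees
WT_HOST_TARGETS = CalibrationTargets(
    mean_run_duration=5.0,
    mean_tumble_duration=3.1,
    tumble_run_time_ratio=0.58,
    speed_ratio=1.8,
    mean_inter_run_angle=56.0,
    persistence=0.68,
    weights={
        "persistence": 3.0,
        "tumble_run_time_ratio": 2.0,
        "mean_inter_run_angle": 0.5,
        "speed_ratio": 1.5,
        "mean_run_duration": 0.5,
        "mean_tumble_duration": 0.5,
    },
)

#: search box around the calibrated control preset
CALIBRATION_SPACE = {
    "tau_r": (1.4, 3.5),
    "tau_t": (0.6, 2.5),
    "v_run_sd": (0.2, 0.8),
    "v_tumble_mean": (2.5, 5.5),
    "v_tumble_sd": (0.4, 1.8),
    "D_theta": (0.01, 0.25),
    "sigma_eps": (0.45, 1.3),
}


def calibrate_to_study(
    targets: CalibrationTargets,
    n_cells: int,
    seed: int,
    budget: int = 160,
    n_ensembles: int = 3,
    reselect_top: int = 12,
) -> CalibrationResult:
    """Calibrate the model against one host-condition target set.

    The search starts from the calibrated control preset and explores
    the box :data:`CALIBRATION_SPACE` around it.  Because the objective
    is a noisy Monte-Carlo estimate, the apparent optimum of the search
    is upward-biased toward its own common-random-number realisation
    (winner's curse); the ``reselect_top`` best trace points are
    therefore re-evaluated on an independent seed set and the final
    parameters are the re-evaluated minimiser.
    """
    from .calibrate import objective

    base = SCENARIO_PRESETS["control"].replace(n_cells=n_cells, seed=seed)
    res = calibrate(
        targets,
        search_space=CALIBRATION_SPACE,
        budget=budget,
        seed=seed,
        base_params=base,
        n_cells=n_cells,
        n_ensembles=n_ensembles,
    )
    if reselect_top > 1:
        ranked = sorted(res.trace, key=lambda kv: kv[1])[:reselect_top]
        fresh_seed = subseed(seed, 999)
        best_kw, best_val = None, np.inf
        for kw, _ in ranked:
            p = base.replace(**kw)
            vals = np.array([
                objective(p, targets, n_cells=n_cells, seed=fresh_seed + e,
                          n_ensembles=1)
                for e in range(6)
            ])
            # mean + spread: prefer parameter regions whose segmented
            # read-outs are stable between realisations, not just good
            # on average
            score = float(vals.mean() + vals.std())
            if score < best_val:
                best_kw, best_val = kw, score
        res.best_params = base.replace(**best_kw)
        res.objective_value = float(best_val)
    return res


def ensemble_readouts(
    params: SimulationParams,
    n_cells: int,
    seed: int,
    total_time: float = 120.0,
    n_batches: int = 1,
) -> dict:
    """Simulate, segment blind, and pool the summary statistics.

    With ``n_batches > 1``, several independently seeded experiments of
    ``n_cells`` cells are simulated and each is segmented against its
    own pooled density (as a real replicate experiment would be); the
    summary statistics pool cells and segments across replicates, which
    averages over the threshold-placement noise of any single density
    realisation.
    """
    import warnings

    p = params.replace(n_cells=n_cells)
    all_trajs, all_anns = [], []
    for b in range(n_batches):
        trajs, _ = simulate_ensemble(p, total_time=total_time,
                                     seed=subseed(seed, b))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, anns = segment_ensemble(trajs)
        all_trajs.extend(trajs)
        all_anns.extend(anns)
    return ensemble_summary(all_trajs, all_anns)


def subseed(seed: int, *key: int) -> int:
    """Derive a deterministic 31-bit sub-seed from a master seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % 2**31)
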