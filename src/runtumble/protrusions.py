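"""Protrusion classification and orientation statistics.

Migrating mesendoderm progenitors form two protrusion types: blebs
(spherical, initially devoid of actin, low surface curvature) and
actin-rich protrusions (filamentous actin throughout expansion, higher
curvature).  This module classifies events from feature flags, measures
how sharply protrusion formation is focused around the migration
direction (polar order parameter), and compares per-phase formation
rates between tumble and run phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .exceptions import ValidationError
from .types import RUN, TUMBLE, PhaseAnnotation, ProtrusionEventRecord

ANGLE_BINS = np.arange(-180.0, 181.0, 20.0)  # 18 bins of 20 degrees


@dataclass
class ProtrusionFeatures:
    """Feature flags of one detected protrusion.

    ``actin_present_throughout``: Lifeact signal during the entire
    expansion; ``peak_curvature`` in 1/um; ``initial_actin``: actin
    present already at initiation.
    """

    actin_present_throughout: bool
    peak_curvature: float
    initial_actin: bool

    def __post_init__(self) -> None:
        if self.peak_curvature < 0:
            raise ValidationError("curvature must be >= 0")


@dataclass
class OrientationSummary:
    pop: float
    pop_sem: float
    n_cells: int
    n_events: int
    weighted: bool
    angle_histogram: np.ndarray
    per_cell_pop: dict


@dataclass
class PhaseFrequencyRatio:
    bleb_ratio: float
    actin_ratio: float
    bleb_sem: float
    actin_sem: float
    per_cell: dict  # cell_id -> {kind: ratio}


def classify_protrusion(
    f: ProtrusionFeatures, curvature_threshold: float
) -> str:
    """Classify one protrusion as actin_rich, bleb or unclassified.

    Actin-rich requires actin throughout the expansion and curvature at
    or above the threshold; a bleb starts without actin and stays below
    the curvature threshold.  Contradictory combinations (high curvature
    without sustained actin) are left unclassified with a warning.
    """
    if f.actin_present_throughout and f.peak_curvature >= curvature_threshold:
        return "actin_rich"
    if not f.initial_actin and f.peak_curvature < curvature_threshold:
        return "bleb"
    warnings.warn(
        "contradictory protrusion features; leaving unclassified", stacklevel=2
    )
    return "unclassified"


def calibrate_curvature_threshold(
    features: list[ProtrusionFeatures], labels: list[str]
) -> float:
    """Pick the curvature threshold best separating labelled features.

    Scans midpoints between sorted curvature values and returns the
    threshold maximising classification accuracy against the given
    bleb/actin_rich labels.
    """
    if len(features) != len(labels) or not features:
        raise ValidationError("features and labels must be non-empty and aligned")
    curvs = np.array([f.peak_curvature for f in features])
    order = np.argsort(curvs)
    cands = [0.0] + [
        0.5 * (curvs[order[i]] + curvs[order[i + 1]]) for i in range(len(curvs) - 1)
    ] + [curvs.max() + 1.0]
    best_thr, best_acc = cands[0], -1.0
    for thr in cands:
        pred = [classify_protrusion_quiet(f, thr) for f in features]
        acc = np.mean([p == l for p, l in zip(pred, labels)])
        if acc > best_acc:
            best_acc, best_thr = acc, thr
    return float(best_thr)


def classify_protrusion_quiet(f: ProtrusionFeatures, thr: float) -> str:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return classify_protrusion(f, thr)


def polar_order_parameter(
    events: list[ProtrusionEventRecord], weighted: bool = False
) -> OrientationSummary:
    """Polar order parameter of protrusion orientations, per cell.

    For each cell, POP is the length of the (weight-)averaged unit
    vector of its event angles: 1 for perfectly focused formation, 0 for
    isotropic.  Returns mean +- SEM across cells plus the pooled
    20-degree angle histogram (counts, or weight sums when weighted).
    """
    if not events:
        raise ValidationError("no protrusion events")
    per_cell: dict[str, float] = {}
    cells: dict[str, list[ProtrusionEventRecord]] = {}
    for e in events:
        cells.setdefault(e.cell_id, []).append(e)
    for cid, evs in cells.items():
        w = np.array([e.weight if weighted else 1.0 for e in evs])
        if weighted and np.any([e.weight is None for e in evs]):
            raise ValidationError("weighted POP requested but weights missing")
        if w.sum() == 0:
            warnings.warn(f"cell {cid} has zero total weight; excluded", stacklevel=2)
            continue
        th = np.radians([e.angle for e in evs])
        vec = np.array([(w * np.cos(th)).sum(), (w * np.sin(th)).sum()]) / w.sum()
        per_cell[cid] = float(np.linalg.norm(vec))
    if not per_cell:
        raise ValidationError("no cells with positive total weight")
    vals = np.array(list(per_cell.values()))
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
    angles = np.array([e.angle for e in events])
    weights = np.array([e.weight if weighted else 1.0 for e in events])
    hist, _ = np.histogram(angles, bins=ANGLE_BINS, weights=weights)
    return OrientationSummary(
        pop=float(vals.mean()),
        pop_sem=sem,
        n_cells=len(vals),
        n_events=len(events),
        weighted=weighted,
        angle_histogram=hist,
        per_cell_pop=per_cell,
    )


def pop_significantly_different(a: OrientationSummary, b: OrientationSummary) -> bool:
    """SEM-overlap criterion: True when the mean +- SEM intervals disjoin."""
    return (a.pop - a.pop_sem > b.pop + b.pop_sem) or (
        b.pop - b.pop_sem > a.pop + a.pop_sem
    )


def von_mises_pop(kappa: float) -> float:
    """Expected POP of a von Mises sample: the Bessel ratio I1(k)/I0(k)."""
    if kappa < 0:
        raise ValidationError("concentration must be >= 0")
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_for_pop(pop: float) -> float:
    """Invert the Bessel ratio: concentration giving the requested POP."""
    if not 0 <= pop < 1:
        raise ValidationError("POP must be in [0, 1)")
    if pop == 0:
        return 0.0
    return float(optimize.brentq(lambda k: von_mises_pop(k) - pop, 1e-9, 1e4))


def _phase_at(ann: PhaseAnnotation, t: float) -> str:
    t0 = ann.segments[0].t_start
    t1 = ann.segments[-1].t_end
    if not (t0 - 1e-9 <= t <= t1 + 1e-9):
        raise ValidationError(
            f"event time {t} outside annotated span [{t0}, {t1}] "
            f"of cell {ann.cell_id}"
        )
    for s in ann.segments:
        if s.t_start - 1e-9 <= t < s.t_end - 1e-9:
            return s.phase
    return ann.segments[-1].phase


def phase_frequency_ratio(
    events: list[ProtrusionEventRecord],
    annotations: dict[str, PhaseAnnotation],
) -> PhaseFrequencyRatio:
    """Tumble-vs-run formation-rate ratio per protrusion type.

    For each cell and kind: (events in tumbles / total tumble time)
    divided by (events in runs / total run time).  Cells with zero run
    or tumble time are excluded with a warning; the aggregate is the
    mean +- SEM of finite per-cell ratios.
    """
    per_cell: dict[str, dict[str, float]] = {}
    by_cell: dict[str, list[ProtrusionEventRecord]] = {}
    for e in events:
        if e.cell_id not in annotations:
            raise ValidationError(f"no annotation for cell {e.cell_id}")
        by_cell.setdefault(e.cell_id, []).append(e)
    for cid, evs in by_cell.items():
        ann = annotations[cid]
        t_run = ann.total_time(RUN)
        t_tum = ann.total_time(TUMBLE)
        if t_run == 0 or t_tum == 0:
            warnings.warn(
                f"cell {cid} lacks a run or tumble phase; excluded", stacklevel=2
            )
            continue
        ratios = {}
        for kind in ("bleb", "actin_rich"):
            kind_evs = [e for e in evs if e.kind == kind]
            if not kind_evs:
                continue
            n_tum = sum(1 for e in kind_evs if _phase_at(ann, e.time) == TUMBLE)
            n_run = len(kind_evs) - n_tum
            rate_tum = n_tum / t_tum
            rate_run = n_run / t_run
            ratios[kind] = rate_tum / rate_run if rate_run > 0 else np.inf
        per_cell[cid] = ratios

    def agg(kind: str) -> tuple[float, float]:
        vals = np.array(
            [r[kind] for r in per_cell.values() if kind in r and np.isfinite(r[kind])]
        )
        if vals.size == 0:
            return np.nan, np.nan
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        return float(vals.mean()), float(sem)

    bleb, bleb_sem = agg("bleb")
    actin, actin_sem = agg("actin_rich")
    return PhaseFrequencyRatio(
        bleb_ratio=bleb,
        actin_ratio=actin,
        bleb_sem=bleb_sem,
        actin_sem=actin_sem,
        per_cell=per_cell,
    )


def front_classification(
    events: list[ProtrusionEventRecord],
) -> tuple[float, dict[str, float]]:
    """Fraction of protrusions forming toward the cell front.

    An event is "front" iff its angle to the local migration direction
    is strictly within 90 degrees.  Returns the pooled fraction and the
    per-cell fractions.
    """
    if not events:
        raise ValidationError("no protrusion events")
    per_cell: dict[str, list[bool]] = {}
    for e in events:
        per_cell.setdefault(e.cell_id, []).append(abs(e.angle) < 90.0)
    fractions = {cid: float(np.mean(v)) for cid, v in per_cell.items()}
    pooled = float(np.mean([abs(e.angle) < 90.0 for e in events]))
    return pooled, fractions


def bleb_size_normalized(projected_area: float, cell_projected_area: float) -> float:
    """Bleb projected area at maximal extension over whole-cell area."""
    if projected_area is None or cell_projected_area is None:
        raise ValidationError("both areas are required")
    if projected_area <= 0 or cell_projected_area <= 0:
        raise ValidationError("areas must be positive")
    return float(projected_area / cell_projected_area)


def rose_plot(summary: OrientationSummary, path=None, ax=None, title: str = ""):
    """Polar histogram (18 x 20-degree bins) of protrusion orientations."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = np.radians(0.5 * (ANGLE_BINS[:-1] + ANGLE_BINS[1:]))
    ax.bar(centers, summary.angle_histogram, width=np.radians(20.0), alpha=0.7)
    label = f"POP = {summary.pop:.3f}"
    if np.isfinite(summary.pop_sem):
        label += f" $\\pm$ {summary.pop_sem:.3f}"
    ax.set_title(f"{title} {label}".strip())
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
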