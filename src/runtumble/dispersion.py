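"""Migration-precision metric: positional variance of co-transplanted groups.

Precision is quantified as the spatial dispersion var(x) + var(y) of
the final positions of a group of cells transplanted together, about
two hours after transplantation.  Perturbed groups are normalised to
the control group of the same embryo (internal controls), and the
per-embryo ratios are tested one-sided against 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

MIN_CELLS_PER_GROUP = 3  # embryos with fewer cells in a group are excluded


@dataclass
class DispersionRecord:
    embryo_id: str
    condition: str
    n_cells: int
    variance: float  # var_x + var_y, um^2
    normalized_ratio: float | None = None


def positional_variance(positions) -> float:
    """Unbiased var(x) + var(y) of 2D final positions, in um^2.

    Rotation- and translation-invariant (the variance sum is the trace
    of the covariance matrix).  Requires at least three cells.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"positions must be (n, 2); got {pts.shape}")
    if len(pts) < MIN_CELLS_PER_GROUP:
        raise ValidationError(
            f"need >= {MIN_CELLS_PER_GROUP} cells, got {len(pts)}"
        )
    if not np.all(np.isfinite(pts)):
        raise ValidationError("non-finite position")
    return float(pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1))


def normalized_dispersion(
    endpoints: pd.DataFrame,
    control_condition: str = "control",
) -> tuple[pd.DataFrame, float, float]:
    """Per-embryo dispersion ratios and a one-sided t test against 1.

    ``endpoints`` columns: ``embryo_id, condition, x_um, y_um``.  Every
    embryo contributes one ratio: experimental variance over the same
    embryo's control variance.  Embryos lacking either group (or with
    fewer than three cells in one) are skipped with a warning.  Returns
    (records, t statistic, one-sided p value) for the alternative that
    ratios exceed 1.
    """
    required = {"embryo_id", "condition", "x_um", "y_um"}
    missing = required - set(endpoints.columns)
    if missing:
        raise ValidationError(f"endpoint table lacks column(s): {sorted(missing)}")
    rows = []
    ratios = []
    for embryo, grp in endpoints.groupby("embryo_id", sort=True):
        conds = grp.groupby("condition")
        if control_condition not in conds.groups:
            warnings.warn(f"embryo {embryo} has no control group; skipped",
                          stacklevel=2)
            continue
        ctrl = conds.get_group(control_condition)
        exp_conds = [c for c in conds.groups if c != control_condition]
        if not exp_conds:
            warnings.warn(f"embryo {embryo} has no experimental group; skipped",
                          stacklevel=2)
            continue
        if len(ctrl) < MIN_CELLS_PER_GROUP:
            warnings.warn(
                f"embryo {embryo}: control group below {MIN_CELLS_PER_GROUP} "
                "cells; skipped", stacklevel=2)
            continue
        var_ctrl = positional_variance(ctrl[["x_um", "y_um"]].to_numpy())
        for cond in exp_conds:
            exp = conds.get_group(cond)
            if len(exp) < MIN_CELLS_PER_GROUP:
                warnings.warn(
                    f"embryo {embryo}: {cond} group below "
                    f"{MIN_CELLS_PER_GROUP} cells; skipped", stacklevel=2)
                continue
            var_exp = positional_variance(exp[["x_um", "y_um"]].to_numpy())
            ratio = var_exp / var_ctrl if var_ctrl > 0 else np.inf
            ratios.append(ratio)
            rows.append(
                DispersionRecord(
                    embryo_id=str(embryo), condition=str(cond),
                    n_cells=len(exp), variance=var_exp,
                    normalized_ratio=float(ratio),
                )
            )
    if not rows:
        raise ValidationError("no embryo satisfied the group-size criterion")
    arr = np.array(ratios, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2 or np.allclose(finite.std(ddof=1), 0):
        warnings.warn("degenerate ratio sample; t test undefined", stacklevel=2)
        t_stat, p = np.nan, np.nan
    else:
        t_stat, p = stats.ttest_1samp(finite, 1.0, alternative="greater")
    records = pd.DataFrame(
        [(r.embryo_id, r.condition, r.n_cells, r.variance, r.normalized_ratio)
         for r in rows],
        columns=["embryo_id", "condition", "n_cells", "variance_um2", "ratio"],
    )
    return records, float(t_stat), float(p)
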