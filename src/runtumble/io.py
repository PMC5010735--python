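"""Reading and writing of track, protrusion-event and annotation tables.

All tables are plain CSV/TSV with case-insensitive headers, times in
minutes, positions in micrometres and angles in degrees.  Canonical
column names are ``cell_id, time_min, x_um, y_um, z_um, condition`` for
tracks; the short aliases ``time, x, y, z`` are accepted on input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .types import (
    PhaseAnnotation,
    ProtrusionEventRecord,
    Trajectory,
)

_TRACK_ALIASES = {
    "time": "time_min",
    "t": "time_min",
    "x": "x_um",
    "y": "y_um",
    "z": "z_um",
}
_EVENT_ALIASES = {
    "time": "time_min",
    "angle": "angle_deg",
    "area": "area_um2",
    "cell_area": "cell_area_um2",
}


def _read_table(path, dialect: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    if dialect not in {"csv", "tsv"}:
        raise FormatError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t" if dialect == "tsv" else ",")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_tracks(path, dialect: str | None = None) -> list[Trajectory]:
    """Load one Trajectory per cell from a CSV/TSV track table.

    Mandatory columns (case-insensitive): ``cell_id``, ``time_min`` (or
    ``time``), ``x_um``/``x`` and ``y_um``/``y``.  ``z`` defaults to 0
    and ``condition`` to ``"control"``.  Rows are sorted by time within
    each cell; duplicate (cell_id, time) pairs are rejected.
    """
    df = _read_table(path, dialect)
    df = df.rename(columns=_TRACK_ALIASES)
    required = ["cell_id", "time_min", "x_um", "y_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"track table lacks mandatory column(s): {missing}")
    if "z_um" not in df.columns:
        df["z_um"] = 0.0
    if "condition" not in df.columns:
        df["condition"] = "control"
    dup = df.duplicated(subset=["cell_id", "time_min"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"duplicate (cell_id, time) at row {row}: "
            f"{df.iloc[row]['cell_id']!r} t={df.iloc[row]['time_min']}"
        )
    trajs = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        cond = str(grp["condition"].iloc[0])
        trajs.append(
            Trajectory(
                cell_id=str(cell_id),
                times=grp["time_min"].to_numpy(dtype=float),
                positions=grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                condition=cond,
            )
        )
    return trajs


def write_tracks(trajs: list[Trajectory], path, dialect: str = "csv") -> None:
    """Write trajectories in the canonical track-table schema."""
    rows = []
    for t in trajs:
        for k in range(len(t)):
            rows.append(
                (t.cell_id, t.times[k], t.positions[k, 0], t.positions[k, 1],
                 t.positions[k, 2], t.condition)
            )
    df = pd.DataFrame(
        rows, columns=["cell_id", "time_min", "x_um", "y_um", "z_um", "condition"]
    )
    df.to_csv(path, sep="\t" if dialect == "tsv" else ",", index=False)


def signed_angle_deg(direction: np.ndarray, vector: np.ndarray) -> float:
    """Angle of ``vector`` relative to ``direction``, degrees in (-180, 180].

    In the x-y plane the angle is signed (counter-clockwise positive);
    when either vector has a z component the unsigned 3D angle between
    them is returned, as the sign is not defined off-plane.
    """
    d = np.asarray(direction, dtype=float)
    v = np.asarray(vector, dtype=float)
    nd, nv = np.linalg.norm(d), np.linalg.norm(v)
    if nd == 0 or nv == 0:
        raise ValidationError("zero-length vector has no angle")
    planar = d.size < 3 or (abs(d[2]) < 1e-12 and abs(v[2]) < 1e-12)
    if planar:
        ang = np.degrees(
            np.arctan2(d[0] * v[1] - d[1] * v[0], d[0] * v[0] + d[1] * v[1])
        )
    else:
        c = np.clip(d @ v / (nd * nv), -1.0, 1.0)
        ang = np.degrees(np.arccos(c))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def read_protrusions(path, dialect: str | None = None) -> list[ProtrusionEventRecord]:
    """Load protrusion events from a CSV/TSV table.

    Either an ``angle_deg`` column is present, or the raw-vector variant
    ``cx,cy,cz`` (cell CoM), ``px,py,pz`` (protrusion CoM) and
    ``dx,dy,dz`` (local migration direction), from which the angle is
    computed.  ``kind`` defaults to ``unclassified``; ``weight`` to 1.
    """
    df = _read_table(path, dialect)
    df = df.rename(columns=_EVENT_ALIASES)
    required = ["cell_id", "time_min"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"protrusion table lacks column(s): {missing}")
    vec_cols = ["cx", "cy", "cz", "px", "py", "pz", "dx", "dy", "dz"]
    has_angle = "angle_deg" in df.columns
    has_vecs = all(c in df.columns for c in vec_cols)
    if not has_angle and not has_vecs:
        raise FormatError(
            "protrusion table needs an angle_deg column or the "
            "cx..dz raw-vector columns"
        )
    records = []
    for _, row in df.iterrows():
        if has_angle and np.isfinite(row.get("angle_deg", np.nan)):
            angle = float(row["angle_deg"])
        else:
            com = np.array([row["cx"], row["cy"], row["cz"]], dtype=float)
            pro = np.array([row["px"], row["py"], row["pz"]], dtype=float)
            direction = np.array([row["dx"], row["dy"], row["dz"]], dtype=float)
            angle = signed_angle_deg(direction, pro - com)
        weight = float(row["weight"]) if "weight" in df.columns and np.isfinite(
            row.get("weight", np.nan)
        ) else 1.0
        area = row.get("area_um2", np.nan)
        cell_area = row.get("cell_area_um2", np.nan)
        records.append(
            ProtrusionEventRecord(
                cell_id=str(row["cell_id"]),
                time=float(row["time_min"]),
                kind=str(row.get("kind", "unclassified"))
                if "kind" in df.columns
                else "unclassified",
                angle=angle,
                weight=weight,
                projected_area=float(area) if np.isfinite(area) else None,
                cell_projected_area=float(cell_area)
                if np.isfinite(cell_area)
                else None,
            )
        )
    return records


def write_protrusions(
    events: list[ProtrusionEventRecord], path, dialect: str = "csv"
) -> None:
    df = pd.DataFrame(
        [
            (e.cell_id, e.time, e.kind, e.angle, e.weight,
             e.projected_area, e.cell_projected_area)
            for e in events
        ],
        columns=["cell_id", "time_min", "kind", "angle_deg", "weight",
                 "area_um2", "cell_area_um2"],
    )
    df.to_csv(path, sep="\t" if dialect == "tsv" else ",", index=False)


def write_annotations(
    annotations: list[PhaseAnnotation],
    path,
    dialect: str = "csv",
    trajectories: list[Trajectory] | None = None,
) -> None:
    """Write per-timepoint phase labels in long format.

    Columns: ``cell_id, time_min, phase, segment_index``.  If matching
    trajectories are supplied, each annotation's times are validated
    against its trajectory before writing.
    """
    if trajectories is not None:
        by_id = {t.cell_id: t for t in trajectories}
        for a in annotations:
            t = by_id.get(a.cell_id)
            if t is not None and (
                len(t.times) != len(a.times) or not np.allclose(t.times, a.times)
            ):
                raise ValidationError(
                    f"annotation times mismatch trajectory for cell {a.cell_id}"
                )
    rows = []
    for a in annotations:
        seg_idx = np.zeros(len(a.times), dtype=int)
        k = 0
        bounds = [s.t_start for s in a.segments] + [np.inf]
        for i, t in enumerate(a.times):
            while t >= bounds[k + 1] - 1e-9:
                k += 1
            seg_idx[i] = k
        for i in range(len(a.times)):
            rows.append((a.cell_id, a.times[i], a.labels[i], seg_idx[i]))
    df = pd.DataFrame(rows, columns=["cell_id", "time_min", "phase", "segment_index"])
    df.to_csv(path, sep="\t" if dialect == "tsv" else ",", index=False)


def read_annotations(path, dialect: str | None = None) -> list[PhaseAnnotation]:
    """Read annotations written by :func:`write_annotations`."""
    df = _read_table(path, dialect)
    required = ["cell_id", "time_min", "phase"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table lacks column(s): {missing}")
    anns = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        anns.append(
            PhaseAnnotation(
                cell_id=str(cell_id),
                times=grp["time_min"].to_numpy(dtype=float),
                labels=grp["phase"].to_numpy(dtype=object),
            )
        )
    return anns
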