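"""CSV/JSON interchange for landmarks, visual-field exams and results tables.

Landmark CSV layout: one row per point, columns
``eye_id, point_role, x_um, y_um, depth_um, laterality, scale_um_per_unit``.
Each eye has one ``header`` row carrying laterality, scale and the BMO-plane
reference depth (in ``depth_um``); ``margin`` rows in delineation order; one
``fovea`` row; at most one ``trunk`` row (absent = trunk outside the BMO; its
``depth_um`` is the axial trunk depth); at most one ``ppa`` row.

Visual-field CSV layout: one row per exam with 52 pattern-deviation category
columns named by grid coordinates (``pd_x-9_y+3``), global indices and the
three reliability rates. Maps are stored in right-eye orientation.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .grid import build_grid_242, scoreable_column_names
from .types import PD_CATEGORIES, PD_LEVELS, EyeSeries, GeometrySummary, LandmarkRecord, VfExam

__all__ = [
    "write_landmarks_csv",
    "read_landmarks_csv",
    "write_vf_exams_csv",
    "read_vf_exams_csv",
    "write_geometry_csv",
]


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return repr(float(v))


def write_landmarks_csv(records: list[LandmarkRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "eye_id": rec.eye_id,
                "point_role": "header",
                "x_um": "",
                "y_um": "",
                "depth_um": _fmt(rec.bmo_plane_depth_um),
                "laterality": rec.laterality,
                "scale_um_per_unit": _fmt(rec.scale_um_per_unit),
            }
        )
        for x, y in rec.bmo_margin:
            rows.append({"eye_id": rec.eye_id, "point_role": "margin",
                         "x_um": _fmt(x), "y_um": _fmt(y), "depth_um": "",
                         "laterality": "", "scale_um_per_unit": ""})
        rows.append({"eye_id": rec.eye_id, "point_role": "fovea",
                     "x_um": _fmt(rec.fovea[0]), "y_um": _fmt(rec.fovea[1]),
                     "depth_um": "", "laterality": "", "scale_um_per_unit": ""})
        if rec.trunk is not None:
            rows.append({"eye_id": rec.eye_id, "point_role": "trunk",
                         "x_um": _fmt(rec.trunk[0]), "y_um": _fmt(rec.trunk[1]),
                         "depth_um": _fmt(rec.trunk_depth_um),
                         "laterality": "", "scale_um_per_unit": ""})
        if rec.ppa_max_point is not None:
            rows.append({"eye_id": rec.eye_id, "point_role": "ppa",
                         "x_um": _fmt(rec.ppa_max_point[0]), "y_um": _fmt(rec.ppa_max_point[1]),
                         "depth_um": "", "laterality": "", "scale_um_per_unit": ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks_csv(path: str | Path) -> list[LandmarkRecord]:
    df = pd.read_csv(path, dtype={"eye_id": str, "point_role": str}, float_precision="round_trip")
    records: list[LandmarkRecord] = []
    for eye_id, g in df.groupby("eye_id", sort=False):
        by_role = dict(tuple(g.groupby("point_role")))
        try:
            header = by_role["header"].iloc[0]
            margin = tuple(
                (float(r.x_um), float(r.y_um)) for r in by_role["margin"].itertuples()
            )
            fv = by_role["fovea"].iloc[0]
        except KeyError as exc:
            raise ValueError(f"{path}: eye {eye_id} missing required {exc} rows") from exc
        trunk = None
        trunk_depth = None
        if "trunk" in by_role:
            tr = by_role["trunk"].iloc[0]
            trunk = (float(tr.x_um), float(tr.y_um))
            trunk_depth = None if pd.isna(tr.depth_um) else float(tr.depth_um)
        ppa = None
        if "ppa" in by_role:
            pr = by_role["ppa"].iloc[0]
            ppa = (float(pr.x_um), float(pr.y_um))
        records.append(
            LandmarkRecord(
                eye_id=str(eye_id),
                laterality=str(header.laterality),
                bmo_margin=margin,
                fovea=(float(fv.x_um), float(fv.y_um)),
                trunk=trunk,
                trunk_depth_um=trunk_depth,
                bmo_plane_depth_um=None if pd.isna(header.depth_um) else float(header.depth_um),
                ppa_max_point=ppa,
                scale_um_per_unit=float(header.scale_um_per_unit),
            )
        )
    return records


def write_vf_exams_csv(exams: list[VfExam], path: str | Path) -> None:
    grid = build_grid_242()
    cols = scoreable_column_names(grid)
    rows = []
    for e in exams:
        row: dict = {"eye_id": e.eye_id, "visit": e.visit}
        for c, lv in zip(cols, e.pd_levels):
            row[c] = PD_CATEGORIES[lv]
        row.update(
            md_db=e.md_db, psd_prob=e.psd_prob, ght=e.ght,
            fixation_loss_rate=e.fixation_loss_rate,
            false_pos_rate=e.false_pos_rate, false_neg_rate=e.false_neg_rate,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_vf_exams_csv(path: str | Path) -> dict[str, list[VfExam]]:
    """Exams grouped by eye, sorted by visit."""
    grid = build_grid_242()
    cols = scoreable_column_names(grid)
    df = pd.read_csv(path, dtype={"eye_id": str}, float_precision="round_trip")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pattern-deviation columns {missing[:3]}...")
    out: dict[str, list[VfExam]] = {}
    for row in df.to_dict("records"):
        levels = tuple(PD_LEVELS[row[c]] for c in cols)

        def rate(v):
            return None if pd.isna(v) else float(v)

        out.setdefault(str(row["eye_id"]), []).append(
            VfExam(
                eye_id=str(row["eye_id"]),
                visit=int(row["visit"]),
                pd_levels=levels,
                md_db=float(row["md_db"]),
                psd_prob=float(row["psd_prob"]),
                ght=str(row["ght"]),
                fixation_loss_rate=rate(row["fixation_loss_rate"]),
                false_pos_rate=rate(row["false_pos_rate"]),
                false_neg_rate=rate(row["false_neg_rate"]),
            )
        )
    for exams in out.values():
        exams.sort(key=lambda e: e.visit)
    return out


def write_geometry_csv(summaries: list[GeometrySummary], path: str | Path) -> None:
    """One row per eye; missing values serialize as empty fields."""
    pd.DataFrame([s.__dict__ for s in summaries]).to_csv(path, index=False)
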