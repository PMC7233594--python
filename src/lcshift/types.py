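"""Domain containers shared across the geometry, visual-field and statistics stages.

Coordinate convention: planar optic-nerve-head landmarks live in a fundus-style
frame with y increasing toward the superior retina. Units are micrometres after
magnification correction. Axial depths (for lamina cribrosa depth) are separate
scalars, positive = posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

Point = tuple[float, float]

LATERALITIES = ("right", "left")


@dataclass(frozen=True)
class LandmarkRecord:
    """One eye's planar optic-nerve-head landmark annotation.

    ``trunk is None`` encodes the vascular trunk lying outside the Bruch's
    membrane opening (BMO); by convention such eyes get shift index 1.0 and no
    angular deviation.
    """

    eye_id: str
    laterality: str
    bmo_margin: tuple[Point, ...]
    fovea: Point
    trunk: Point | None = None
    trunk_depth_um: float | None = None
    bmo_plane_depth_um: float | None = None
    ppa_max_point: Point | None = None
    scale_um_per_unit: float = 1.0

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise ValueError(
                f"unknown laterality {self.laterality!r}; expected one of {LATERALITIES}"
            )
        if len(self.bmo_margin) < 8:
            raise ValueError(
                f"BMO margin needs >=8 delineated points, got {len(self.bmo_margin)}"
            )
        if self.scale_um_per_unit <= 0:
            raise ValueError("scale_um_per_unit must be positive")

    @property
    def margin_array(self) -> np.ndarray:
        return np.asarray(self.bmo_margin, dtype=float)


@dataclass(frozen=True)
class GeometrySummary:
    """Derived per-eye geometry: trunk position metrics and BMO morphometry.

    ``alpha_deg`` — signed angular deviation of the vascular trunk from the
    nasal horizontal midline, right-eye orientation, positive superior; missing
    (None) for severe shift (trunk outside the BMO).
    ``shift_index`` — centre-to-trunk distance over centre-to-margin distance
    along the same ray, in [0, 1]; exactly 1.0 under the outside-BMO convention.
    ``beta_deg`` — angular location of maximal beta-zone parapapillary atrophy
    width from the temporal midline, positive superior.
    ``obliqueness_deg`` — in-quadrant angle of the trunk from the horizontal
    (0 = horizontal, 90 = vertical).
    ``lcd_um`` — lamina cribrosa depth at the trunk: axial distance from the
    BMO plane.
    """

    eye_id: str
    alpha_deg: float | None
    shift_index: float
    shift_group: str
    beta_deg: float | None
    obliqueness_deg: float | None
    lcd_um: float | None
    bmo_area_mm2: float


PD_CATEGORIES = ("normal", "p<5%", "p<2%", "p<1%", "p<0.5%")
#: numeric codes for pattern-deviation probability categories, 0 = normal.
PD_LEVELS = {name: level for level, name in enumerate(PD_CATEGORIES)}

GHT_VALUES = ("within", "borderline", "outside")


@dataclass(frozen=True)
class VfExam:
    """One visit's Humphrey 24-2 result in right-eye orientation.

    ``pd_levels`` holds one probability-category code per scoreable grid point
    (blind-spot points excluded), ordered as in :func:`lcshift.grid.build_grid_242`.
    """

    eye_id: str
    visit: int
    pd_levels: tuple[int, ...]
    md_db: float
    psd_prob: float
    ght: str
    fixation_loss_rate: float | None
    false_pos_rate: float | None
    false_neg_rate: float | None

    def __post_init__(self) -> None:
        if len(self.pd_levels) != 52:
            raise ValueError(f"expected 52 scoreable-point categories, got {len(self.pd_levels)}")
        if any(not 0 <= v <= 4 for v in self.pd_levels):
            raise ValueError("pattern-deviation category codes must be in 0..4")
        if self.ght not in GHT_VALUES:
            raise ValueError(f"unknown GHT flag {self.ght!r}")
        for name in ("fixation_loss_rate", "false_pos_rate", "false_neg_rate"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0 or math.isnan(v)):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class EyeSeries:
    """Longitudinal record for one study eye: exams sorted by visit plus covariates."""

    eye_id: str
    exams: list[VfExam] = field(default_factory=list)
    covariates: dict[str, float | str] = field(default_factory=dict)

    def sorted_exams(self) -> list[VfExam]:
        return sorted(self.exams, key=lambda e: e.visit)


@dataclass(frozen=True)
class HemisphereCall:
    """Outcome of the defect-cluster rule on a single exam."""

    label: str  # none | superior | inferior | bi
    clusters: tuple[tuple[str, frozenset[int]], ...] = ()


def as_point(obj: Sequence[float]) -> Point:
    x, y = float(obj[0]), float(obj[1])
    return (x, y)
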