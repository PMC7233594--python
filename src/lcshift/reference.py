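"""Published-cohort summary statistics used as recomputation fixtures.

These are the shift-group-stratified demographics of a published clinical
cohort of 81 myopic high-tension glaucoma eyes (38 mild-shift, 37
moderate-shift, 6 severe-shift). Only group sizes, means/SDs and category
counts are recorded — no patient-level data exist here. They let the
summary-statistics ANOVA, Scheffe post hoc, pooled t and chi-square routines
be exercised against a table whose p-values are known.
"""

from __future__ import annotations

from .stats import GroupSummary

N_EYES = 81
GROUP_NS = {"A": 38, "B": 37, "C": 6}

#: continuous rows: group label -> (n, mean, sd); compared by one-way ANOVA
CONTINUOUS_ROWS: dict[str, list[GroupSummary]] = {
    "age": [
        GroupSummary("A", 38, 60.3, 11.6),
        GroupSummary("B", 37, 51.5, 14.6),
        GroupSummary("C", 6, 38.8, 8.8),
    ],
    "highest_iop": [
        GroupSummary("A", 38, 25.6, 5.0),
        GroupSummary("B", 37, 25.1, 3.2),
        GroupSummary("C", 6, 23.8, 2.9),
    ],
    "axial_length": [
        GroupSummary("A", 38, 25.0, 1.0),
        GroupSummary("B", 37, 25.9, 1.5),
        GroupSummary("C", 6, 26.4, 1.0),
    ],
    "md_initial": [
        GroupSummary("A", 38, -8.37, 5.86),
        GroupSummary("B", 37, -7.80, 6.05),
        GroupSummary("C", 6, -8.41, 5.33),
    ],
    "md_final": [
        GroupSummary("A", 38, -10.90, 6.58),
        GroupSummary("B", 37, -10.31, 6.57),
        GroupSummary("C", 6, -9.65, 7.52),
    ],
    "followup_years": [
        GroupSummary("A", 38, 5.1, 2.7),
        GroupSummary("B", 37, 5.1, 2.8),
        GroupSummary("C", 6, 3.3, 1.8),
    ],
    "bmo_area_mm2": [
        GroupSummary("A", 38, 2.42, 0.56),
        GroupSummary("B", 37, 2.90, 1.23),
        GroupSummary("C", 6, 2.65, 0.70),
    ],
}

#: two-group rows (severe-shift eyes have no measurable trunk): pooled t test
TWO_GROUP_ROWS: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "abs_angular_deviation": (
        GroupSummary("A", 38, 37.7, 42.8),
        GroupSummary("B", 37, 30.8, 44.1),
    ),
    "lcd_um": (
        GroupSummary("A", 38, 546.0, 150.0),
        GroupSummary("B", 37, 531.0, 165.0),
    ),
}

#: categorical rows: shift group x outcome counts; compared by chi-square
CATEGORICAL_ROWS: dict[str, list[list[int]]] = {
    # male / female
    "sex": [[29, 9], [23, 14], [4, 2]],
    # bi-hemispheric VF defect yes / no at initial visits
    "bihemi_vf_initial": [[7, 31], [7, 30], [4, 2]],
    # bi-hemispheric VF defect yes / no at final visits
    "bihemi_vf_final": [[15, 23], [15, 22], [4, 2]],
    # bi-hemispheric RNFL defect yes / no at final visits
    "bihemi_rnfl_final": [[29, 9], [30, 7], [6, 0]],
}

#: eyes with bi-hemispheric retinal-nerve-fibre-layer defects at final visits
BIHEMI_RNFL_COUNTS = (29, 30, 6)
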