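"""Defect-cluster rule and hemisphere assignment for 24-2 pattern-deviation maps.

A localized glaucomatous defect is a connected set of abnormal pattern-
deviation points within one hemifield: at least ``min_size`` points at or
beyond the abnormality threshold, of which at least one reaches the stricter
threshold. The default ("methods") rule is 3 connected points at p < 5% with
one at p < 1%; a stricter named alternative ("abstract") requires all points
at p < 0.5%. Connectivity on the 6-degree lattice is 8-neighbour by default,
and clusters never span the horizontal meridian.

Longitudinally, a hemifield's defect is established once its qualifying
cluster is seen in ``confirm_n`` consecutive reliable exams (default 2,
mirroring confirmation of defects on two consecutive reliable tests). The
initial hemisphere is the first to establish; if both establish at the same
exam — including at presentation — the eye is bi-hemispheric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .grid import Grid242, build_grid_242
from .types import EyeSeries, HemisphereCall, VfExam

__all__ = [
    "ClusterRule",
    "METHODS_RULE",
    "ABSTRACT_RULE",
    "is_reliable",
    "find_clusters",
    "hemifield_call",
    "is_glaucomatous_defect",
    "initial_hemisphere",
    "final_hemisphere",
]

#: reliability cut-offs (inclusive): fixation losses <= 20%, FP/FN errors <= 25%
MAX_FIXATION_LOSS = 0.20
MAX_FALSE_POS = 0.25
MAX_FALSE_NEG = 0.25


@dataclass(frozen=True)
class ClusterRule:
    """Parameters of the connected-abnormal-points rule.

    ``abnormal_level``/``strict_level`` are pattern-deviation category codes
    (0 normal, 1 p<5%, 2 p<2%, 3 p<1%, 4 p<0.5%).
    """

    name: str
    min_size: int = 3
    abnormal_level: int = 1  # p < 5%
    strict_level: int = 3  # at least one point at p < 1%
    n_strict: int = 1
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.min_size < 1 or not 1 <= self.abnormal_level <= 4:
            raise ValueError("invalid cluster rule parameters")
        if not self.abnormal_level <= self.strict_level <= 4:
            raise ValueError("strict level must be at least the abnormal level")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


METHODS_RULE = ClusterRule(name="methods")
ABSTRACT_RULE = ClusterRule(name="abstract", abnormal_level=4, strict_level=4)

RULES = {"methods": METHODS_RULE, "abstract": ABSTRACT_RULE}


def is_reliable(exam: VfExam) -> bool:
    """True iff fixation loss <= 20% and both error rates <= 25% (inclusive)."""
    rates = (exam.fixation_loss_rate, exam.false_pos_rate, exam.false_neg_rate)
    if any(r is None or r != r for r in rates):
        warnings.warn(f"exam {exam.eye_id}/{exam.visit}: missing reliability index, treated as unreliable", stacklevel=2)
        return False
    fl, fp, fn = rates
    return fl <= MAX_FIXATION_LOSS and fp <= MAX_FALSE_POS and fn <= MAX_FALSE_NEG


def _levels_by_grid_index(exam: VfExam, grid: Grid242) -> dict[int, int]:
    return {p.index: lv for p, lv in zip(grid.scoreable, exam.pd_levels)}


def find_clusters(
    exam: VfExam, grid: Grid242 | None = None, rule: ClusterRule = METHODS_RULE
) -> list[tuple[str, frozenset[int]]]:
    """Qualifying defect clusters of an exam as ``(hemifield, grid-index set)``.

    Returns maximal connected components of abnormal points computed within
    each hemifield (blind-spot points excluded), keeping only components that
    satisfy the size and stricter-point conditions. Ordering is deterministic:
    superior hemifield first, then by smallest member index.
    """
    grid = grid or build_grid_242()
    levels = _levels_by_grid_index(exam, grid)
    adj = grid.adjacency(rule.connectivity)
    abnormal = {i for i, lv in levels.items() if lv >= rule.abnormal_level}
    hemis = {p.index: p.hemifield for p in grid.points}

    out: list[tuple[str, frozenset[int]]] = []
    seen: set[int] = set()
    for start in sorted(abnormal):
        if start in seen:
            continue
        stack, comp = [start], {start}
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb in abnormal and nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        n_strict = sum(levels[i] >= rule.strict_level for i in comp)
        if len(comp) >= rule.min_size and n_strict >= rule.n_strict:
            out.append((hemis[start], frozenset(comp)))
    out.sort(key=lambda c: (c[0] != "superior", min(c[1])))
    return out


def hemifield_call(
    exam: VfExam, grid: Grid242 | None = None, rule: ClusterRule = METHODS_RULE
) -> HemisphereCall:
    """Label an exam none/superior/inferior/bi by which hemifields hold a qualifying cluster."""
    clusters = find_clusters(exam, grid, rule)
    hemis = {h for h, _ in clusters}
    if hemis == {"superior", "inferior"}:
        label = "bi"
    elif hemis:
        label = next(iter(hemis))
    else:
        label = "none"
    return HemisphereCall(label=label, clusters=tuple(clusters))


def is_glaucomatous_defect(exam: VfExam, grid: Grid242 | None = None) -> bool:
    """Glaucomatous visual-field defect criterion.

    True iff the glaucoma hemifield test is outside normal limits, OR a
    qualifying cluster exists in either hemifield (5%/1% rule), OR the pattern
    standard deviation probability is below 5%.
    """
    if exam.ght == "outside":
        return True
    if exam.psd_prob < 0.05:
        return True
    return bool(find_clusters(exam, grid, METHODS_RULE))


def _established_at(
    calls: list[set[str]], hemifield: str, confirm_n: int
) -> int | None:
    """Index of the reliable exam at which ``hemifield`` completes its run of
    ``confirm_n`` consecutive appearances, or None."""
    run = 0
    for i, hemis in enumerate(calls):
        run = run + 1 if hemifield in hemis else 0
        if run >= confirm_n:
            return i
    return None


def initial_hemisphere(
    series: EyeSeries,
    rule: ClusterRule = METHODS_RULE,
    confirm_n: int = 2,
    grid: Grid242 | None = None,
) -> str:
    """First hemisphere in which a confirmed defect appears.

    Scans reliable exams chronologically; a hemifield establishes once its
    qualifying cluster appears in ``confirm_n`` consecutive reliable exams.
    Returns that hemifield, ``bi`` if both establish at the same exam, or
    ``undetermined`` when neither does (or fewer than 2 reliable exams exist).
    """
    grid = grid or build_grid_242()
    reliable = [e for e in series.sorted_exams() if is_reliable(e)]
    if len(reliable) < 2:
        warnings.warn(f"eye {series.eye_id}: fewer than 2 reliable exams; hemisphere undetermined", stacklevel=2)
        return "undetermined"
    calls = [{h for h, _ in find_clusters(e, grid, rule)} for e in reliable]
    sup = _established_at(calls, "superior", confirm_n)
    inf = _established_at(calls, "inferior", confirm_n)
    if sup is None and inf is None:
        return "undetermined"
    if sup is not None and (inf is None or sup < inf):
        return "superior"
    if inf is not None and (sup is None or inf < sup):
        return "inferior"
    return "bi"


def final_hemisphere(
    series: EyeSeries,
    rule: ClusterRule = METHODS_RULE,
    confirm_n: int = 2,
    grid: Grid242 | None = None,
) -> str:
    """Hemisphere status over the last ``confirm_n`` reliable exams.

    A hemifield counts only if its qualifying cluster is present in every one
    of those exams; returns none/superior/inferior/bi accordingly.
    """
    grid = grid or build_grid_242()
    reliable = [e for e in series.sorted_exams() if is_reliable(e)]
    if len(reliable) < 2:
        warnings.warn(f"eye {series.eye_id}: fewer than 2 reliable exams; final hemisphere none", stacklevel=2)
        return "none"
    tail = reliable[-confirm_n:]
    calls = [{h for h, _ in find_clusters(e, grid, rule)} for e in tail]
    confirmed = set.intersection(*calls) if calls else set()
    if confirmed == {"superior", "inferior"}:
        return "bi"
    if confirmed:
        return next(iter(confirmed))
    return "none"
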