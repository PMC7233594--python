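"""Self-validation studies: simulation-based parameter recovery and
independent-route cross-checks of the core numerics.

Each function runs the package's own machinery against either a known ground
truth (simulation studies) or an independently coded oracle (dense boundary
sampling for the shift index, exhaustive component enumeration for the
visual-field cluster rule, raw-data ANOVA for the summary-statistics ANOVA)
and reports an agreement metric. They exist so that a deployment can
re-certify the numerics from scratch with one call each.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ctree import ctree_fit
from .grid import Grid242, build_grid_242
from .simulate import SimConfig, _draw_alpha, _draw_truth, simulate_covariates, simulate_onset_labels
from .stats import GroupSummary, anova_from_summary, logistic_fit
from .types import VfExam
from . import geometry, vf

__all__ = [
    "logistic_recovery_study",
    "ctree_hierarchy_study",
    "shift_index_oracle_study",
    "cluster_rule_agreement_study",
    "anova_raw_agreement_study",
]


def logistic_recovery_study(
    n_replicates: int = 200,
    n_per_cohort: int = 2000,
    config: SimConfig | None = None,
    seed: int = 0,
) -> dict:
    """Repeatedly fit the inferior-onset logistic model on cohorts drawn from
    its own truth and report estimate quality.

    Returns the mean estimated odds ratio per degree, the fraction of
    replicates whose Wald 95% CI covers the true value, and the true value.
    """
    config = config or SimConfig()
    true_or = math.exp(config.effect_logodds_per_degree)
    rng = np.random.default_rng([seed % (2**31), 101])
    estimates, covered = [], 0
    for _ in range(n_replicates):
        df = simulate_onset_labels(n_per_cohort, config, rng)
        res = logistic_fit({"alpha": df.alpha}, df.inferior)
        estimates.append(res.odds_ratio["alpha"])
        covered += res.ci_low["alpha"] <= true_or <= res.ci_high["alpha"]
    return {
        "true_or": true_or,
        "mean_or": float(np.mean(estimates)),
        "coverage": covered / n_replicates,
        "n_replicates": n_replicates,
        "n_per_cohort": n_per_cohort,
    }


def ctree_hierarchy_study(
    n_replicates: int = 100,
    n_per_cohort: int = 200,
    config: SimConfig | None = None,
    seed: int = 0,
    n_perm: int = 999,
) -> dict:
    """Fraction of replicate cohorts in which the tree recovers the generative
    hierarchy: trunk angle at the root, baseline MD at the next level.

    Each cohort draws covariates and onset labels from the generator's truth
    model (angle drives the superior/inferior side; worse baseline MD drives
    bi-hemispheric onset), then fits the conditional-inference tree on
    (angle, baseline MD).
    """
    config = config or SimConfig()
    rng = np.random.default_rng([seed % (2**31), 202])
    hits = 0
    for _ in range(n_replicates):
        cov = simulate_covariates(n_per_cohort, config, rng)
        alpha = np.array([_draw_alpha(rng, config) for _ in range(n_per_cohort)])
        onset = [
            _draw_truth(rng, config, a, 0.3, md)["onset"]
            for a, md in zip(alpha, cov.md0)
        ]
        X = pd.DataFrame({"alpha_deg": alpha, "md0": cov.md0.to_numpy()})
        tree = ctree_fit(X, np.array(onset), alpha=0.05, n_perm=n_perm,
                         seed=int(rng.integers(2**31)))
        ok = tree.split_var == "alpha_deg" and any(
            child is not None and child.split_var == "md0"
            for child in (tree.left, tree.right)
        )
        hits += ok
    return {"recovery_rate": hits / n_replicates, "n_replicates": n_replicates,
            "n_per_cohort": n_per_cohort}


def _dense_boundary_distance(center, direction, poly, n_samples: int = 4096) -> float:
    """Oracle for the centre-to-margin distance: dense boundary sampling plus
    bisection on the boundary parameter, independent of exact ray/segment
    intersection."""
    pts = np.asarray(poly, float)
    n = len(pts)
    c = np.asarray(center, float)
    d = np.asarray(direction, float)
    d = d / np.hypot(*d)

    def boundary(t):  # t in [0, n): linear interpolation along edges
        i = int(t) % n
        frac = t - int(t)
        return pts[i] + frac * (pts[(i + 1) % n] - pts[i])

    def angle_cross(t):
        v = boundary(t) - c
        return d[0] * v[1] - d[1] * v[0]

    ts = np.linspace(0, n, n_samples, endpoint=False)
    best = None
    for k in range(n_samples):
        t0, t1 = ts[k], ts[(k + 1) % n_samples] if k + 1 < n_samples else n
        c0, c1 = angle_cross(t0), angle_cross(t1)
        if c0 == 0.0:
            cand = boundary(t0)
        elif c0 * c1 < 0:
            lo, hi = t0, t1
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if angle_cross(lo) * angle_cross(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            cand = boundary(0.5 * (lo + hi))
        else:
            continue
        v = cand - c
        if v @ d > 0:  # keep crossings on the forward ray only
            dist = float(np.hypot(*v))
            best = dist if best is None else min(best, dist)
    if best is None:
        raise RuntimeError("dense-sampling oracle found no boundary crossing")
    return best


def shift_index_oracle_study(n_cases: int = 60, seed: int = 0) -> dict:
    """Maximum disagreement of the shift index against two oracles.

    Circle cases compare against the closed form a/r; convex-polygon cases
    against the dense-sampling boundary oracle (relative error).
    """
    rng = np.random.default_rng([seed % (2**31), 303])
    max_err_circle = 0.0
    for _ in range(n_cases):
        r = rng.uniform(500, 1200)
        poly = tuple((r * math.cos(2 * math.pi * k / 1440), r * math.sin(2 * math.pi * k / 1440))
                     for k in range(1440))
        # aim the trunk ray through a delineated margin point, where the
        # piecewise-linear margin coincides with the circle exactly
        th = 2 * math.pi * int(rng.integers(1440)) / 1440
        a = rng.uniform(0, 0.95 * r)
        si = geometry.shift_index((0, 0), (a * math.cos(th), a * math.sin(th)), poly)
        max_err_circle = max(max_err_circle, abs(si - a / r))

    max_rel_err_poly = 0.0
    for _ in range(n_cases):
        # random convex polygon: convex hull of random points
        from scipy.spatial import ConvexHull

        pts = rng.normal(0, 800, size=(30, 2))
        hull = ConvexHull(pts)
        poly = tuple(map(tuple, pts[hull.vertices]))
        c = geometry.bmo_centroid(poly)
        th = rng.uniform(0, 2 * math.pi)
        direction = (math.cos(th), math.sin(th))
        b_oracle = _dense_boundary_distance(c, direction, poly)
        a = rng.uniform(0.05, 0.95) * b_oracle
        trunk = (c[0] + a * direction[0], c[1] + a * direction[1])
        si = geometry.shift_index(c, trunk, poly)
        rel = abs(si - a / b_oracle) / (a / b_oracle)
        max_rel_err_poly = max(max_rel_err_poly, rel)
    return {"max_abs_err_circle": max_err_circle,
            "max_rel_err_polygon": max_rel_err_poly, "n_cases": n_cases}


def _enumerate_clusters_oracle(levels_by_index: dict[int, int], grid: Grid242,
                               rule: vf.ClusterRule) -> set[frozenset[int]]:
    """Exhaustive connected-component enumeration via pairwise Chebyshev
    adjacency and union-find, independent of the production BFS."""
    pos = {p.index: (p.x_deg, p.y_deg, p.hemifield) for p in grid.scoreable}
    abnormal = [i for i, lv in levels_by_index.items() if lv >= rule.abnormal_level]
    parent = {i: i for i in abnormal}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in abnormal:
        for j in abnormal:
            if i >= j or pos[i][2] != pos[j][2]:
                continue
            dx = abs(pos[i][0] - pos[j][0]) // 6
            dy = abs(pos[i][1] - pos[j][1]) // 6
            adjacent = max(dx, dy) == 1 if rule.connectivity == 8 else dx + dy == 1
            if adjacent:
                parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in abnormal:
        comps.setdefault(find(i), set()).add(i)
    out = set()
    for comp in comps.values():
        strict = sum(levels_by_index[i] >= rule.strict_level for i in comp)
        if len(comp) >= rule.min_size and strict >= rule.n_strict:
            out.add(frozenset(comp))
    return out


def cluster_rule_agreement_study(n_maps: int = 1000, seed: int = 0,
                                 rule: vf.ClusterRule = vf.METHODS_RULE) -> dict:
    """Fraction of random 24-2 maps on which the production cluster finder and
    the exhaustive enumeration oracle return identical qualifying clusters."""
    grid = build_grid_242()
    rng = np.random.default_rng([seed % (2**31), 404])
    agree = 0
    for _ in range(n_maps):
        density = rng.random() * 0.5
        levels = {p.index: (int(rng.integers(1, 5)) if rng.random() < density else 0)
                  for p in grid.scoreable}
        exam = VfExam(
            eye_id="m", visit=0,
            pd_levels=tuple(levels[p.index] for p in grid.scoreable),
            md_db=0.0, psd_prob=1.0, ght="within",
            fixation_loss_rate=0.0, false_pos_rate=0.0, false_neg_rate=0.0,
        )
        got = {members for _, members in vf.find_clusters(exam, grid, rule)}
        want = _enumerate_clusters_oracle(levels, grid, rule)
        agree += got == want
    return {"agreement_rate": agree / n_maps, "n_maps": n_maps}


def anova_raw_agreement_study(n_datasets: int = 200, seed: int = 0) -> dict:
    """Maximum |p - p_raw| between the summary-statistics ANOVA and raw-data
    one-way ANOVA on random datasets sharing the same summaries."""
    rng = np.random.default_rng([seed % (2**31), 505])
    max_err = 0.0
    for _ in range(n_datasets):
        k = int(rng.integers(2, 5))
        raw = [rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), int(rng.integers(5, 40)))
               for _ in range(k)]
        gs = [GroupSummary(str(i), len(x), float(np.mean(x)), float(np.std(x, ddof=1)))
              for i, x in enumerate(raw)]
        f_raw, p_raw = sps.f_oneway(*raw)
        f, _, _, p = anova_from_summary(gs)
        max_err = max(max_err, abs(p - p_raw), abs(f - f_raw) / max(abs(f_raw), 1.0))
    return {"max_abs_err": max_err, "n_datasets": n_datasets}
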