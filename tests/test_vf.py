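import numpy as np
import pytest

from lcshift import vf
from lcshift.grid import build_grid_242
from lcshift.types import EyeSeries

from conftest import make_exam


class TestGrid:
    def test_layout_counts(self, grid):
        assert len(grid.points) == 54
        assert sum(p.blind_spot for p in grid.points) == 2
        assert len(grid.scoreable_indices("superior")) == 26
        assert len(grid.scoreable_indices("inferior")) == 26

    def test_blind_spot_position(self, grid):
        bs = {(p.x_deg, p.y_deg) for p in grid.points if p.blind_spot}
        assert bs == {(15, 3), (15, -3)}

    def test_adjacency_never_crosses_meridian(self, grid):
        hemis = {p.index: p.hemifield for p in grid.points}
        for i, nbrs in grid.adjacency(8).items():
            assert all(hemis[j] == hemis[i] for j in nbrs)

    def test_four_connectivity_is_subset_of_eight(self, grid):
        a4, a8 = grid.adjacency(4), grid.adjacency(8)
        assert all(a4[i] <= a8[i] for i in a4)


class TestReliability:
    @pytest.mark.parametrize(
        "fl,fp,fn,ok",
        [
            (0.20, 0.25, 0.25, True),  # inclusive thresholds
            (0.21, 0.00, 0.00, False),
            (0.00, 0.26, 0.00, False),
            (0.00, 0.00, 0.26, False),
            (0.0, 0.0, 0.0, True),
        ],
    )
    def test_thresholds(self, fl, fp, fn, ok):
        e = make_exam(fixation_loss_rate=fl, false_pos_rate=fp, false_neg_rate=fn)
        assert vf.is_reliable(e) is ok

    def test_missing_rate_is_unreliable_with_warning(self):
        e = make_exam(fixation_loss_rate=None)
        with pytest.warns(UserWarning, match="reliability"):
            assert vf.is_reliable(e) is False


class TestFindClusters:
    def test_three_adjacent_with_strict_point_qualifies(self, grid):
        e = make_exam({(-9, 9): 1, (-3, 9): 1, (3, 9): 3})
        out = vf.find_clusters(e, grid)
        assert len(out) == 1
        hemifield, members = out[0]
        assert hemifield == "superior" and len(members) == 3

    def test_two_points_never_qualify(self, grid):
        e = make_exam({(-9, 9): 4, (-3, 9): 4})
        assert vf.find_clusters(e, grid) == []

    def test_no_strict_point_disqualifies(self, grid):
        e = make_exam({(-9, 9): 1, (-3, 9): 2, (3, 9): 1})
        assert vf.find_clusters(e, grid) == []

    def test_hemifield_confinement_across_meridian(self, grid):
        # 2 superior + 1 inferior abnormal points meeting across the meridian
        e = make_exam({(-9, 3): 4, (-3, 3): 4, (-3, -3): 4})
        assert vf.find_clusters(e, grid) == []

    def test_blind_spot_never_bridges(self, grid):
        # points flanking the blind spot column are not 4/8-connected through it
        e = make_exam({(9, 3): 4, (21, 3): 4, (15, 9): 4})
        out = vf.find_clusters(e, grid)
        # (9,3)-(15,9)-(21,3) are mutually diagonal: 8-connectivity joins them
        assert len(out) == 1
        e4 = make_exam({(9, 3): 4, (21, 3): 4})
        assert vf.find_clusters(e4, grid, vf.ClusterRule(name="m4", connectivity=4)) == []

    def test_abstract_rule_requires_p005(self, grid):
        e = make_exam({(-9, 9): 3, (-3, 9): 3, (3, 9): 3})
        assert vf.find_clusters(e, grid, vf.METHODS_RULE)
        assert vf.find_clusters(e, grid, vf.ABSTRACT_RULE) == []
        e2 = make_exam({(-9, 9): 4, (-3, 9): 4, (3, 9): 4})
        assert vf.find_clusters(e2, grid, vf.ABSTRACT_RULE)

    def test_monotone_in_abnormality(self, grid):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pos = {(p.x_deg, p.y_deg): int(rng.integers(0, 5) * (rng.random() < 0.3))
                   for p in grid.scoreable}
            e = make_exam(pos)
            before = {frozenset(m) for _, m in vf.find_clusters(e, grid)}
            # escalate one random point to the worst category
            keys = list(pos)
            k = keys[int(rng.integers(len(keys)))]
            pos[k] = 4
            worse = make_exam(pos)
            after = {frozenset(m) for _, m in vf.find_clusters(worse, grid)}
            # every qualifying cluster remains covered by some qualifying cluster
            for comp in before:
                assert any(comp <= c for c in after)


def brute_force_clusters(levels_by_pos, grid, rule):
    """Independent oracle: pairwise Chebyshev adjacency + BFS via networkx."""
    import networkx as nx

    g = nx.Graph()
    pts = {p.index: (p.x_deg, p.y_deg, p.hemifield) for p in grid.scoreable}
    abnormal = [i for i in pts
                if levels_by_pos.get((pts[i][0], pts[i][1]), 0) >= rule.abnormal_level]
    g.add_nodes_from(abnormal)
    for i in abnormal:
        for j in abnormal:
            if i >= j:
                continue
            xi, yi, hi = pts[i]
            xj, yj, hj = pts[j]
            if hi != hj:
                continue
            dx, dy = abs(xi - xj) // 6, abs(yi - yj) // 6
            if rule.connectivity == 8 and max(dx, dy) == 1:
                g.add_edge(i, j)
            if rule.connectivity == 4 and dx + dy == 1:
                g.add_edge(i, j)
    out = set()
    for comp in nx.connected_components(g):
        lv = [levels_by_pos.get((pts[i][0], pts[i][1]), 0) for i in comp]
        if len(comp) >= rule.min_size and sum(v >= rule.strict_level for v in lv) >= rule.n_strict:
            out.add(frozenset(comp))
    return out


class TestClusterOracle:
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_equals_exhaustive_enumeration(self, grid, connectivity):
        rule = vf.ClusterRule(name="t", connectivity=connectivity)
        rng = np.random.default_rng(123)
        for _ in range(300):
            dense = rng.random() * 0.5
            pos = {}
            for p in grid.scoreable:
                if rng.random() < dense:
                    pos[(p.x_deg, p.y_deg)] = int(rng.integers(1, 5))
            e = make_exam(pos)
            got = {m for _, m in vf.find_clusters(e, grid, rule)}
            want = brute_force_clusters(pos, grid, rule)
            assert got == want


class TestHemifieldCall:
    def test_superior_only(self, grid):
        e = make_exam({(-9, 9): 4, (-3, 9): 4, (3, 9): 4})
        assert vf.hemifield_call(e, grid).label == "superior"

    def test_both_is_bi(self, grid):
        e = make_exam({(-9, 9): 4, (-3, 9): 4, (3, 9): 4,
                       (-9, -9): 4, (-3, -9): 4, (3, -9): 4})
        assert vf.hemifield_call(e, grid).label == "bi"

    def test_none(self, grid):
        assert vf.hemifield_call(make_exam(), grid).label == "none"


class TestGlaucomatousDefect:
    def test_ght_outside_alone(self, grid):
        assert vf.is_glaucomatous_defect(make_exam(ght="outside"), grid)

    def test_psd_prob_alone(self, grid):
        assert vf.is_glaucomatous_defect(make_exam(psd_prob=0.04), grid)

    def test_two_abnormal_points_insufficient(self, grid):
        e = make_exam({(-9, 9): 4, (-3, 9): 4}, psd_prob=0.5)
        assert not vf.is_glaucomatous_defect(e, grid)


SUP = {(-9, 9): 4, (-3, 9): 4, (3, 9): 4}
INF = {(-9, -9): 4, (-3, -9): 4, (3, -9): 4}


def series(maps, eye_id="e1", **kw):
    exams = [make_exam(m, visit=i, eye_id=eye_id, **kw) for i, m in enumerate(maps)]
    return EyeSeries(eye_id=eye_id, exams=exams)


class TestInitialHemisphere:
    def test_first_established_single_hemifield(self):
        s = series([SUP, SUP, {**SUP, **INF}, {**SUP, **INF}])
        assert vf.initial_hemisphere(s) == "superior"

    def test_bi_at_presentation(self):
        s = series([{**SUP, **INF}, {**SUP, **INF}])
        assert vf.initial_hemisphere(s) == "bi"

    def test_no_defect_is_undetermined(self):
        assert vf.initial_hemisphere(series([{}, {}])) == "undetermined"

    def test_single_unconfirmed_appearance_not_established(self):
        s = series([SUP, {}, INF, INF])
        assert vf.initial_hemisphere(s) == "inferior"

    def test_fewer_than_two_reliable_warns(self):
        s = series([SUP, SUP], fixation_loss_rate=0.5)
        with pytest.warns(UserWarning, match="reliable"):
            assert vf.initial_hemisphere(s) == "undetermined"

    def test_unreliable_exams_skipped_not_imputed(self):
        bad = make_exam(INF, visit=0, fixation_loss_rate=0.9)
        good = [make_exam(SUP, visit=i) for i in (1, 2)]
        s = EyeSeries(eye_id="e1", exams=[bad] + good)
        assert vf.initial_hemisphere(s) == "superior"

    def test_invariant_to_appending_after_established(self):
        base = [SUP, SUP]
        s0 = series(base)
        for extra in ([INF, INF], [{**SUP, **INF}] * 3, [{}] * 2):
            assert vf.initial_hemisphere(series(base + extra)) == vf.initial_hemisphere(s0)

    def test_confirm_n_three(self):
        s = series([SUP, SUP, INF, INF, INF])
        assert vf.initial_hemisphere(s, confirm_n=3) == "inferior"


class TestFinalHemisphere:
    def test_bi_tail(self):
        s = series([SUP, {**SUP, **INF}, {**SUP, **INF}])
        assert vf.final_hemisphere(s) == "bi"

    def test_inferior_tail(self):
        s = series([SUP, SUP, INF, INF])
        assert vf.final_hemisphere(s) == "inferior"

    def test_alternating_tail_unconfirmed(self):
        s = series([SUP, SUP, SUP, INF])
        assert vf.final_hemisphere(s) == "none"

    def test_monotone_series_keeps_bi(self):
        # bi at presentation stays bi for a non-improving series
        s = series([{**SUP, **INF}] * 4)
        assert vf.initial_hemisphere(s) == "bi"
        assert vf.final_hemisphere(s) == "bi"
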