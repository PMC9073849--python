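"""Matching, P/R/F1, adjudication, NRI and ERL against independent oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from connqa import (
    TerminalAssignment,
    ValidationError,
    adjudicate,
    dedup_keypoints,
    expected_run_length,
    match_keypoints,
    nri,
    precision_recall_f1,
    variance_curve,
)

RES_ISO = (1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def brute_force_match(test_nm, truth_nm, max_dist):
    """Exhaustive optimum: most pairs under threshold, then least total cost."""
    nt, ng = len(test_nm), len(truth_nm)
    best = (0, 0.0)
    for k in range(min(nt, ng), -1, -1):
        best_cost = None
        for t_sub in itertools.combinations(range(nt), k):
            for g_perm in itertools.permutations(range(ng), k):
                dists = [
                    np.linalg.norm(test_nm[i] - truth_nm[j])
                    for i, j in zip(t_sub, g_perm)
                ]
                if any(d > max_dist for d in dists):
                    continue
                cost = sum(dists)
                if best_cost is None or cost < best_cost:
                    best_cost = cost
        if best_cost is not None:
            return k, best_cost
    return 0, 0.0


def brute_force_dedup(points_nm, radius):
    kept = []
    for p in points_nm:
        if all(np.linalg.norm(p - q) > radius for q in kept):
            kept.append(p)
    return np.asarray(kept) if kept else np.empty((0, 3))


def brute_force_nri(truth, test):
    terminals = sorted(truth)
    tp = fp = fn = 0
    for a, b in itertools.combinations(terminals, 2):
        in_truth = truth[a] == truth[b]
        in_test = test[a] == test[b]
        tp += in_truth and in_test
        fp += in_test and not in_truth
        fn += in_truth and not in_test
    denom = 2 * tp + fp + fn
    return (2 * tp / denom if denom else 1.0), tp, fp, fn


# ---------------------------------------------------------------------------
# Dedup
# ---------------------------------------------------------------------------


class TestDedup:
    def test_coincident_points_collapse_to_one(self):
        out = dedup_keypoints([(1, 1, 1), (1, 1, 1)], 10.0, RES_ISO)
        assert len(out) == 1

    def test_zero_radius_keeps_everything_but_exact_duplicates(self):
        pts = [(0, 0, 0), (0, 0, 0), (0.5, 0, 0), (1, 1, 1)]
        out = dedup_keypoints(pts, 0.0, RES_ISO)
        assert len(out) == 3

    def test_matches_greedy_brute_force_on_random_points(self):
        rng = np.random.default_rng(7)
        for radius in (5.0, 20.0, 60.0):
            pts = rng.uniform(0, 100, size=(50, 3))
            ours = dedup_keypoints(pts, radius, RES_ISO)
            oracle = brute_force_dedup(pts, radius)
            np.testing.assert_allclose(ours, oracle)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


class TestMatchKeypoints:
    def test_identical_sets_pair_at_zero_distance(self):
        pts = np.random.default_rng(0).uniform(0, 50, size=(6, 3))
        m = match_keypoints(pts, pts, RES_ISO, max_dist_nm=10)
        assert m.tp == 6 and m.fp == 0 and m.fn == 0
        assert m.total_distance() == pytest.approx(0.0)

    def test_empty_test_side_leaves_truth_unmatched(self):
        truth = np.arange(21).reshape(7, 3)
        m = match_keypoints(np.empty((0, 3)), truth, RES_ISO, 10)
        assert m.pairs == [] and m.unmatched_truth == list(range(7))

    @pytest.mark.parametrize("dissolve", ["before", "after"])
    def test_small_instances_match_brute_force_cost(self, dissolve):
        """Total paired distance equals the exhaustive-permutation minimum."""
        rng = np.random.default_rng(13)
        for _ in range(60):
            nt, ng = rng.integers(0, 6, size=2) + 1
            res = rng.uniform(1, 20, size=3)
            test = rng.uniform(0, 30, size=(nt, 3))
            truth = rng.uniform(0, 30, size=(ng, 3))
            max_dist = float(rng.uniform(30, 250))
            m = match_keypoints(test, truth, res, max_dist, dissolve="before")
            k, cost = brute_force_match(test * res, truth * res, max_dist)
            assert m.tp == k
            assert m.total_distance() == pytest.approx(cost, abs=1e-8)

    def test_anisotropic_scaling_changes_pairing_as_oracle_predicts(self):
        """Stretching z by 10 re-ranks candidate pairs exactly like the oracle."""
        test = np.array([[0, 0, 0], [10.0, 0, 2.0]])
        truth = np.array([[0, 0, 2.0], [10.0, 0, 0]])
        for res in [(1.0, 1.0, 1.0), (1.0, 1.0, 10.0)]:
            m = match_keypoints(test, truth, res, max_dist_nm=50)
            k, cost = brute_force_match(test * np.array(res), truth * np.array(res), 50)
            assert m.tp == k
            assert m.total_distance() == pytest.approx(cost)


# ---------------------------------------------------------------------------
# Metrics and adjudication
# ---------------------------------------------------------------------------


class TestPrecisionRecallF1:
    def test_textbook_counts(self):
        r = precision_recall_f1((3, 1, 2))
        assert r.precision == pytest.approx(0.75)
        assert r.recall == pytest.approx(0.6)
        assert r.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_all_zero_counts_use_zero_convention(self):
        r = precision_recall_f1((0, 0, 0))
        assert (r.precision, r.recall, r.f1) == (0.0, 0.0, 0.0)

    def test_perfect_match_scores_one(self):
        r = precision_recall_f1((9, 0, 0))
        assert (r.precision, r.recall, r.f1) == (1.0, 1.0, 1.0)

    def test_f1_bounded_by_precision_and_recall(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            tp, fp, fn = (int(v) for v in rng.integers(0, 30, size=3))
            r = precision_recall_f1((tp, fp, fn))
            if r.precision + r.recall > 0:
                assert min(r.precision, r.recall) - 1e-12 <= r.f1
                assert r.f1 <= max(r.precision, r.recall) + 1e-12


class TestAdjudication:
    def _match(self):
        # 2 paired, 2 unmatched test (fp), 1 unmatched truth (fn)
        test = np.array([[0, 0, 0], [5, 0, 0], [50, 50, 50], [80, 80, 80.0]])
        truth = np.array([[0, 0, 0], [5, 0, 0], [200, 0, 0.0]])
        return match_keypoints(test, truth, RES_ISO, max_dist_nm=10)

    def test_overturned_fp_becomes_tp(self):
        m = self._match()
        r = adjudicate(m, [("fp", m.unmatched_test[0], "overturn", "expert")])
        assert (r.tp, r.fp) == (m.tp + 1, m.fp - 1)

    def test_ambiguous_fn_is_removed_from_counts(self):
        m = self._match()
        r = adjudicate(m, [("fn", m.unmatched_truth[0], "ambiguous", "expert")])
        assert r.fn == m.fn - 1
        assert r.ambiguous_removed == 1
        assert r.tp == m.tp

    def test_confirm_everything_reproduces_raw_report(self):
        m = self._match()
        overrides = [("fp", i, "confirm", "e") for i in m.unmatched_test]
        overrides += [("fn", j, "confirm", "e") for j in m.unmatched_truth]
        r = adjudicate(m, overrides)
        raw = precision_recall_f1(m)
        assert (r.tp, r.fp, r.fn, r.f1) == (raw.tp, raw.fp, raw.fn, raw.f1)

    def test_override_on_matched_index_rejected(self):
        m = self._match()
        paired_test = m.pairs[0][0]
        with pytest.raises(ValidationError):
            adjudicate(m, [("fp", paired_test, "overturn", "e")])


# ---------------------------------------------------------------------------
# NRI
# ---------------------------------------------------------------------------


class TestNri:
    def test_identical_assignment_scores_one(self):
        a = TerminalAssignment({"t1": "A", "t2": "A", "t3": "B"})
        assert nri(a, a).nri == 1.0

    def test_lone_cell_split_two_plus_two_scores_half(self):
        truth = TerminalAssignment({f"t{i}": "A" for i in range(4)})
        test = TerminalAssignment({"t0": "X", "t1": "X", "t2": "Y", "t3": "Y"})
        r = nri(truth, test)
        assert (r.tp, r.fn, r.fp) == (2, 4, 0)
        assert r.nri == pytest.approx(0.5)

    def test_merging_two_singleton_cells_scores_zero(self):
        truth = TerminalAssignment({"t1": "A", "t2": "B"})
        test = TerminalAssignment({"t1": "M", "t2": "M"})
        r = nri(truth, test)
        assert (r.tp, r.fp, r.fn) == (0, 1, 0)
        assert r.nri == 0.0

    def test_mismatched_terminal_universe_rejected(self):
        with pytest.raises(ValidationError):
            nri(TerminalAssignment({"t1": "A"}), TerminalAssignment({"t2": "A"}))

    def test_matches_exhaustive_pair_counting_on_random_worlds(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            n_terms = int(rng.integers(2, 21))
            n_cells = int(rng.integers(1, 9))
            truth = {f"t{i}": f"c{rng.integers(n_cells)}" for i in range(n_terms)}
            test = {f"t{i}": f"s{rng.integers(n_cells)}" for i in range(n_terms)}
            r = nri(TerminalAssignment(truth), TerminalAssignment(test))
            score, tp, fp, fn = brute_force_nri(truth, test)
            assert (r.tp, r.fp, r.fn) == (tp, fp, fn)
            assert r.nri == pytest.approx(score)

    def test_split_of_a_plus_b_loses_a_times_b_pairs(self):
        rng = np.random.default_rng(5)
        for a, b in [(1, 1), (2, 3), (4, 4), (1, 7)]:
            truth = {f"t{i}": "A" for i in range(a + b)}
            test = {f"t{i}": ("L" if i < a else "R") for i in range(a + b)}
            r = nri(TerminalAssignment(truth), TerminalAssignment(test))
            assert r.fn == a * b


# ---------------------------------------------------------------------------
# ERL
# ---------------------------------------------------------------------------


def path_skeleton(breaks_nm):
    """Path with vertices at given 1-D positions (nm); ids 0..n-1."""
    g = nx.Graph()
    for i, x in enumerate(breaks_nm):
        g.add_node(i, position=(x, 0.0, 0.0))
    for i in range(len(breaks_nm) - 1):
        g.add_edge(i, i + 1, length_nm=float(breaks_nm[i + 1] - breaks_nm[i]))
    return g


class TestErl:
    def test_uniform_correct_label_gives_full_length(self):
        g = path_skeleton([0, 2000, 5000, 10_000])
        r = expected_run_length({"s": g}, {"s": {v: "seg1" for v in g.nodes}})
        assert r.erl_nm == pytest.approx(10_000)
        assert r.total_length_nm == pytest.approx(10_000)

    def test_midpoint_split_of_ten_micron_path_gives_five_microns(self):
        # vertices at 0, 4.5, 5.5, 10 um; the mixed middle edge splits evenly
        g = path_skeleton([0, 4500, 5500, 10_000])
        labels = {0: "a", 1: "a", 2: "b", 3: "b"}
        r = expected_run_length({"s": g}, {"s": labels})
        assert sorted(l for _, l in r.run_lengths) == pytest.approx([5000, 5000])
        assert r.erl_nm == pytest.approx(5000)

    def test_merge_scores_strictly_below_same_split_structure(self):
        g1 = path_skeleton([0, 4500, 5500, 10_000])
        g2 = path_skeleton([0, 5000, 10_000])
        labels_split = {"s1": {0: "a", 1: "a", 2: "b", 3: "b"},
                        "s2": {0: "c", 1: "c", 2: "c"}}
        no_merge = expected_run_length({"s1": g1, "s2": g2}, labels_split)
        labels_merge = {"s1": {0: "a", 1: "a", 2: "c", 3: "c"},
                        "s2": {0: "c", 1: "c", 2: "c"}}
        merged = expected_run_length({"s1": g1, "s2": g2}, labels_merge)
        assert merged.erl_nm < no_merge.erl_nm

    def test_branched_tree_with_one_label_gives_full_cable_length(self):
        g = nx.Graph()
        for i, pos in enumerate([(0, 0, 0), (1000, 0, 0), (2000, 0, 0), (1000, 1000, 0)]):
            g.add_node(i, position=pos)
        g.add_edge(0, 1, length_nm=1000.0)
        g.add_edge(1, 2, length_nm=1000.0)
        g.add_edge(1, 3, length_nm=1000.0)
        r = expected_run_length({"s": g}, {"s": {v: "x" for v in g.nodes}})
        assert r.erl_nm == pytest.approx(3000.0)

    def test_unlabeled_vertex_rejected(self):
        g = path_skeleton([0, 1000])
        with pytest.raises(ValidationError):
            expected_run_length({"s": g}, {"s": {0: "a"}})


# ---------------------------------------------------------------------------
# Variance curve
# ---------------------------------------------------------------------------


class TestVarianceCurve:
    def test_constant_scores_have_zero_variance(self):
        curve = variance_curve([0.8] * 30, [1, 5, 10], n_boot=200, seed=0)
        assert all(v == 0.0 for _, v in curve)

    def test_variance_shrinks_with_sample_size(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0.3, 1.0, size=50)
        curve = dict(variance_curve(scores, [1, 25], n_boot=2000, seed=2))
        assert curve[25] < curve[1]

    def test_tracks_one_over_s_law(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(0.2, 1.0, size=100)
        pop_var = scores.var()
        for s, v in variance_curve(scores, [5, 10, 20], n_boot=4000, seed=3):
            assert v == pytest.approx(pop_var / s, rel=0.2)
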