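"""Scoring of test annotations against reference annotations.

Keypoint (synapse) sets are compared by optimal bipartite matching on
anisotropy-corrected Euclidean distance: voxel coordinates are scaled per
axis by the volume's nm-per-voxel resolution before any distance is taken,
so a coarse z axis is weighted by its true physical extent.  Matched /
unmatched counts feed precision, recall and F1, with an expert adjudication
pass that can overturn or discard individual false positives and negatives.

Neurite traces are compared at the connectome level with two metrics:

* **NRI** (neural reconstruction integrity) — an F-score over unordered
  pairs of synaptic terminals co-assigned to the same cell.  A split error
  destroys truth pairs (false negatives); a merge error fabricates test
  pairs (false positives).  ``NRI = 2·TP / (2·TP + FP + FN)``.

* **ERL** (expected run length) — the expected error-free distance along
  the ground-truth skeletons.  Each skeleton is partitioned into *runs*:
  maximal connected subtrees whose vertices share one test segment label.
  A run whose label also appears on another skeleton is a merge and counts
  as zero traversable length.  ERL is the cable-length-weighted mean run
  length, which for a merge-free labeling equals sum(len^2)/sum(len).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import ValidationError

DEFAULT_MAX_DIST_NM = 400.0
DEFAULT_DEDUP_RADIUS_NM = 100.0


def to_nm(points, resolution) -> np.ndarray:
    """Scale voxel coordinates to nanometers, axis by axis."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    res = np.asarray(resolution, dtype=float)
    if np.any(res <= 0):
        raise ValidationError(f"resolution must be positive, got {tuple(res)}")
    return pts * res


# ---------------------------------------------------------------------------
# Keypoint matching
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    """Outcome of optimal keypoint matching under a distance threshold."""

    pairs: list[tuple[int, int, float]]          # (test idx, truth idx, dist nm)
    unmatched_test: list[int]                    # candidate false positives
    unmatched_truth: list[int]                   # candidate false negatives
    max_dist_nm: float

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_test)

    @property
    def fn(self) -> int:
        return len(self.unmatched_truth)

    def total_distance(self) -> float:
        return float(sum(d for _, _, d in self.pairs))


def dedup_keypoints(points, radius_nm: float, resolution) -> np.ndarray:
    """Greedy duplicate suppression in file order.

    A point is dropped when a previously kept point lies within
    ``radius_nm`` (physical distance).  The survivor set therefore has no
    two points within the radius, and every dropped point is within the
    radius of a survivor.
    """
    if radius_nm < 0:
        raise ValidationError("radius_nm must be >= 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        return pts
    nm = to_nm(pts, resolution)
    kept: list[int] = []
    for i in range(len(pts)):
        if kept:
            d = np.linalg.norm(nm[kept] - nm[i], axis=1)
            if np.any(d <= radius_nm):
                continue
        kept.append(i)
    return pts[kept]


def match_keypoints(
    test,
    truth,
    resolution,
    max_dist_nm: float = DEFAULT_MAX_DIST_NM,
    dissolve: str = "before",
) -> MatchResult:
    """Optimal one-to-one matching of test to truth keypoints.

    Coordinates are scaled to nm per axis before distances are computed
    (anisotropy correction), then a minimum-cost assignment is solved.

    ``dissolve`` controls how the distance threshold interacts with the
    assignment: ``"before"`` (default) makes over-threshold pairings
    prohibitively expensive *before* solving, so the solver maximizes the
    number of feasible pairs and minimizes their total distance;
    ``"after"`` solves on raw distances and then dissolves any resulting
    pair longer than the threshold.
    """
    if dissolve not in ("before", "after"):
        raise ValidationError(f"dissolve must be 'before' or 'after', got {dissolve!r}")
    test_nm = to_nm(test, resolution)
    truth_nm = to_nm(truth, resolution)
    nt, ng = len(test_nm), len(truth_nm)
    if nt == 0 or ng == 0:
        return MatchResult([], list(range(nt)), list(range(ng)), max_dist_nm)

    cost = cdist(test_nm, truth_nm)
    if dissolve == "before":
        # Any prohibitive pairing must cost more than every feasible
        # assignment combined, so feasible pairs are always preferred.
        prohibitive = max_dist_nm * (min(nt, ng) + 1.0) + 1.0
        solve_cost = np.where(cost > max_dist_nm, prohibitive, cost)
    else:
        solve_cost = cost
    rows, cols = linear_sum_assignment(solve_cost)

    pairs = []
    matched_t, matched_g = set(), set()
    for i, j in zip(rows, cols):
        d = float(cost[i, j])
        if d <= max_dist_nm:
            pairs.append((int(i), int(j), d))
            matched_t.add(int(i))
            matched_g.add(int(j))
    return MatchResult(
        pairs=pairs,
        unmatched_test=[i for i in range(nt) if i not in matched_t],
        unmatched_truth=[j for j in range(ng) if j not in matched_g],
        max_dist_nm=max_dist_nm,
    )


# ---------------------------------------------------------------------------
# Precision / recall / F1 and expert adjudication
# ---------------------------------------------------------------------------


@dataclass
class ScoreReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    ambiguous_removed: int = 0
    adjudications: list[tuple] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "ambiguous_removed": self.ambiguous_removed,
            "adjudications": [list(a) for a in self.adjudications],
        }


def precision_recall_f1(match_or_counts) -> ScoreReport:
    """Compute P, R, F1 from a MatchResult or a ``(tp, fp, fn)`` triple.

    Empty denominators yield 0 rather than NaN, so an empty test set
    against a non-empty truth scores P = F1 = 0.
    """
    if isinstance(match_or_counts, MatchResult):
        tp, fp, fn = match_or_counts.tp, match_or_counts.fp, match_or_counts.fn
    else:
        tp, fp, fn = (int(v) for v in match_or_counts)
    if min(tp, fp, fn) < 0:
        raise ValidationError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return ScoreReport(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1)


def adjudicate(match: MatchResult, overrides: Sequence[tuple]) -> ScoreReport:
    """Apply expert rulings to candidate errors and recompute the metrics.

    Each override is ``(side, index, ruling, adjudicator)`` where ``side``
    is ``"fp"`` (an unmatched test point) or ``"fn"`` (an unmatched truth
    point) and ``ruling`` is ``confirm`` (keep as error), ``overturn``
    (the annotation was actually correct: count as a true positive), or
    ``ambiguous`` (remove from all counts).
    """
    paired_t = {i for i, _, _ in match.pairs}
    paired_g = {j for _, j, _ in match.pairs}
    fp_set = set(match.unmatched_test)
    fn_set = set(match.unmatched_truth)
    tp = match.tp
    ambiguous = 0
    adjudications = []
    for side, index, ruling, adjudicator in overrides:
        if side not in ("fp", "fn"):
            raise ValidationError(f"override side must be 'fp' or 'fn', got {side!r}")
        if ruling not in ("confirm", "overturn", "ambiguous"):
            raise ValidationError(f"unknown ruling {ruling!r}")
        pool = fp_set if side == "fp" else fn_set
        paired = paired_t if side == "fp" else paired_g
        if index in paired:
            raise ValidationError(f"override targets matched {side} index {index}")
        if index not in pool:
            raise ValidationError(f"index {index} is not an unmatched {side} candidate")
        if ruling == "confirm":
            adjusted = side
        elif ruling == "overturn":
            pool.discard(index)
            tp += 1
            adjusted = "tp"
        else:
            pool.discard(index)
            ambiguous += 1
            adjusted = "removed"
        adjudications.append((index, side, adjusted, adjudicator))
    report = precision_recall_f1((tp, len(fp_set), len(fn_set)))
    report.ambiguous_removed = ambiguous
    report.adjudications = adjudications
    return report


# ---------------------------------------------------------------------------
# NRI
# ---------------------------------------------------------------------------


@dataclass
class TerminalAssignment:
    """Maps every synaptic terminal to the cell (segment) that owns it."""

    cell_of: dict[str, str]

    @property
    def terminals(self) -> list[str]:
        return list(self.cell_of)

    def cells(self) -> set[str]:
        return set(self.cell_of.values())


@dataclass
class NriResult:
    nri: float
    tp: int
    fp: int
    fn: int


def _co_assigned_pairs(cell_of: Mapping[str, str]) -> int:
    counts: dict[str, int] = {}
    for cell in cell_of.values():
        counts[cell] = counts.get(cell, 0) + 1
    return sum(n * (n - 1) // 2 for n in counts.values())


def nri(truth: TerminalAssignment, test: TerminalAssignment) -> NriResult:
    """Neural reconstruction integrity of ``test`` against ``truth``.

    Over all unordered terminal pairs, TP counts pairs co-assigned in both
    mappings, FP pairs co-assigned only in test (merges), FN pairs
    co-assigned only in truth (splits).  NRI = 2TP / (2TP + FP + FN); a
    reconstruction with no pair errors scores 1.
    """
    t_map, s_map = truth.cell_of, test.cell_of
    if set(t_map) != set(s_map):
        missing = set(t_map) ^ set(s_map)
        raise ValidationError(f"terminal universes differ: {sorted(missing)[:5]} ...")
    joint: dict[tuple[str, str], int] = {}
    for term, t_cell in t_map.items():
        key = (t_cell, s_map[term])
        joint[key] = joint.get(key, 0) + 1
    tp = sum(n * (n - 1) // 2 for n in joint.values())
    fn = _co_assigned_pairs(t_map) - tp
    fp = _co_assigned_pairs(s_map) - tp
    denom = 2 * tp + fp + fn
    score = 2 * tp / denom if denom > 0 else 1.0
    return NriResult(nri=score, tp=tp, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# Expected run length
# ---------------------------------------------------------------------------


@dataclass
class ErlResult:
    erl_nm: float
    run_lengths: list[tuple[str, float]]   # (skeleton id, traversable run length nm)
    total_length_nm: float


def expected_run_length(
    truth_skeletons: Mapping[str, nx.Graph],
    test_label_of_vertex: Mapping[str, Mapping],
) -> ErlResult:
    """Length-weighted expected error-free run length over truth skeletons.

    ``truth_skeletons`` maps skeleton id to a tree whose edges carry a
    ``length_nm`` attribute; ``test_label_of_vertex`` maps skeleton id to
    a per-vertex test segment label.  A *run* is a maximal connected
    subtree whose vertices share one label.  An edge whose endpoints
    disagree is an error locus; its length is split evenly between the two
    adjacent runs (the error is located at the edge midpoint).  A label
    appearing on more than one skeleton is a merge: its runs keep their
    cable weight but traverse zero distance.
    """
    # which labels appear on multiple skeletons (merges)
    label_skels: dict = {}
    for sid, graph in truth_skeletons.items():
        labels = test_label_of_vertex.get(sid, {})
        for v in graph.nodes:
            if v not in labels or labels[v] is None:
                raise ValidationError(f"skeleton {sid}: vertex {v} has no test label")
            label_skels.setdefault(labels[v], set()).add(sid)
    merged_labels = {lab for lab, s in label_skels.items() if len(s) > 1}

    runs: list[tuple[str, float, bool]] = []   # (skeleton, weight, is_merged)
    for sid, graph in truth_skeletons.items():
        labels = test_label_of_vertex[sid]
        same = nx.Graph()
        same.add_nodes_from(graph.nodes)
        boundary_half: dict = {v: 0.0 for v in graph.nodes}
        for u, v, data in graph.edges(data=True):
            length = float(data["length_nm"])
            if labels[u] == labels[v]:
                same.add_edge(u, v, length_nm=length)
            else:
                boundary_half[u] += length / 2.0
                boundary_half[v] += length / 2.0
        for comp in nx.connected_components(same):
            weight = sum(
                d["length_nm"] for _, _, d in same.subgraph(comp).edges(data=True)
            )
            weight += sum(boundary_half[v] for v in comp)
            label = labels[next(iter(comp))]
            runs.append((sid, weight, label in merged_labels))

    total = sum(w for _, w, _ in runs)
    if total <= 0:
        return ErlResult(erl_nm=0.0, run_lengths=[], total_length_nm=0.0)
    traversable = [(sid, 0.0 if merged else w) for sid, w, merged in runs]
    erl = sum(w * t for (_, w, _), (_, t) in zip(runs, traversable)) / total
    return ErlResult(erl_nm=float(erl), run_lengths=traversable, total_length_nm=float(total))


# ---------------------------------------------------------------------------
# Sampling-variance diagnostics
# ---------------------------------------------------------------------------


def variance_curve(
    per_volume_scores: Sequence[float],
    sample_sizes: Sequence[int],
    n_boot: int = 1000,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Bootstrap variance of the mean score as a function of sample size.

    For each size ``s``, draws ``n_boot`` resamples (with replacement) of
    ``s`` volumes and reports the variance of the resample means.  Under
    independent sampling this tracks (population variance) / s, showing how
    many assessment volumes are needed for a stable dataset-level score.
    """
    scores = np.asarray(per_volume_scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("per_volume_scores must be non-empty")
    rng = np.random.default_rng(seed)
    out = []
    for s in sample_sizes:
        if s < 1 or s > scores.size:
            raise ValidationError(f"sample size {s} outside [1, {scores.size}]")
        means = rng.choice(scores, size=(n_boot, s), replace=True).mean(axis=1)
        out.append((int(s), float(means.var())))
    return out
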