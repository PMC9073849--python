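"""Decision fusion: combining many annotators into one consensus annotation.

Atomic proofreading tasks are deliberately small and redundant: the same
subvolume is annotated by several non-experts (typically five), and their
responses are fused so the consensus approaches expert quality.  Three
kinds of responses are fused here:

* **keypoints** — point sets (synapse centers) are clustered across
  annotators by single-linkage agglomeration with a physical radius
  cutoff; a cluster supported by at least ``agreement_min`` distinct
  annotators (the deployed default is 3 of 5) emits one consensus point
  at the cluster centroid;
* **forced-choice verdicts** — yes/no/maybe votes are fused by margin
  majority, with "maybe" treated as abstention-with-signal and close
  calls flagged ``undecided`` for expert escalation;
* **graphs** — skeleton fragments are fused by merging nearby vertices
  across annotators and keeping edges drawn by enough annotators; the
  same vertex-merging machinery stitches fragments from *adjacent,
  overlapping* task volumes into one connected trace.

All distances are computed in nanometers after per-axis resolution
scaling, exactly as in the scoring module.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree

from .errors import ConfigurationError, EmptyInputError, ValidationError
from .sampling import BoundingBox
from .scoring import to_nm

DEFAULT_CLUSTER_RADIUS_NM = 300.0
DEFAULT_NODE_MERGE_RADIUS_NM = 300.0


@dataclass
class KeypointSet:
    """One annotator's point response for a task volume (voxel coords)."""

    annotator: str
    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ConsensusKeypoint:
    position: tuple[float, float, float]   # voxel coords (cluster centroid)
    support: int
    contributors: list[str]


@dataclass
class FusedVerdict:
    verdict: str                 # yes | no | undecided
    votes: dict[str, int]        # counts per literal incl. maybe
    confidence: float            # fraction of non-maybe votes agreeing


def _single_linkage_labels(points_nm: np.ndarray, radius_nm: float) -> np.ndarray:
    """Cluster ids from single-linkage agglomeration with a distance cutoff."""
    n = len(points_nm)
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.zeros(1, dtype=int)
    z = linkage(points_nm, method="single")
    return fcluster(z, t=radius_nm, criterion="distance")


def fuse_keypoints(
    annotator_sets: Sequence[KeypointSet],
    agreement_min: int,
    cluster_radius_nm: float = DEFAULT_CLUSTER_RADIUS_NM,
    resolution=(1.0, 1.0, 1.0),
) -> list[ConsensusKeypoint]:
    """Fuse several annotators' keypoint sets into consensus points.

    Points from distinct annotators within ``cluster_radius_nm`` of each
    other (single linkage) form a cluster; within a cluster each annotator
    contributes at most one point — the one nearest the cluster centroid —
    and clusters reaching ``agreement_min`` distinct annotators emit a
    consensus keypoint at the centroid of the contributing points.
    """
    if not annotator_sets:
        raise EmptyInputError("at least one annotator set is required")
    if agreement_min > len(annotator_sets):
        raise ConfigurationError(
            f"agreement_min={agreement_min} exceeds the {len(annotator_sets)} annotator sets"
        )
    if cluster_radius_nm <= 0:
        raise ValidationError("cluster_radius_nm must be > 0")

    all_pts, owners = [], []
    for ks in annotator_sets:
        for p in ks.points:
            all_pts.append(p)
            owners.append(ks.annotator)
    if not all_pts:
        return []
    pts = np.asarray(all_pts, dtype=float)
    nm = to_nm(pts, resolution)
    labels = _single_linkage_labels(nm, cluster_radius_nm)

    consensus = []
    for cid in np.unique(labels):
        idx = np.nonzero(labels == cid)[0]
        centroid = nm[idx].mean(axis=0)
        # one point per annotator: keep the one closest to the centroid
        best: dict[str, int] = {}
        for i in idx:
            d = float(np.linalg.norm(nm[i] - centroid))
            if owners[i] not in best or d < best[owners[i]][0]:
                best[owners[i]] = (d, i)
        kept = [i for _, i in best.values()]
        if len(best) < agreement_min:
            continue
        pos_nm = nm[kept].mean(axis=0)
        pos_vox = pos_nm / np.asarray(resolution, dtype=float)
        consensus.append(
            ConsensusKeypoint(
                position=tuple(float(v) for v in pos_vox),
                support=len(best),
                contributors=sorted(best),
            )
        )
    return consensus


def fuse_forced_choice(
    decisions: Iterable,
    min_votes: int = 1,
    margin: int = 1,
) -> FusedVerdict:
    """Fuse yes/no/maybe votes into one verdict by margin majority.

    "maybe" votes are recorded but excluded from the margin computation.
    The fused verdict is the majority literal when the majority beats the
    minority by at least ``margin`` votes and at least ``min_votes``
    non-maybe votes were cast; otherwise ``undecided``, which downstream
    workflows escalate to an expert.
    """
    verdicts = [d.verdict if hasattr(d, "verdict") else d for d in decisions]
    if not verdicts:
        raise EmptyInputError("decisions must be non-empty")
    for v in verdicts:
        if v not in ("yes", "no", "maybe"):
            raise ValidationError(f"unknown verdict literal {v!r}")
    votes = {"yes": 0, "no": 0, "maybe": 0}
    for v in verdicts:
        votes[v] += 1
    yes, no = votes["yes"], votes["no"]
    decisive = yes + no
    majority = "yes" if yes >= no else "no"
    maj, mino = max(yes, no), min(yes, no)
    if decisive >= min_votes and (maj - mino) >= margin:
        verdict = majority
        confidence = maj / decisive
    else:
        verdict = "undecided"
        confidence = maj / decisive if decisive else 0.0
    return FusedVerdict(verdict=verdict, votes=votes, confidence=confidence)


# ---------------------------------------------------------------------------
# Graph fusion
# ---------------------------------------------------------------------------


def _positions_nm(graph: nx.Graph, resolution) -> dict:
    return {
        v: to_nm(np.asarray(graph.nodes[v]["position"]), resolution)[0]
        for v in graph.nodes
    }


def fuse_graphs(
    annotator_graphs: Sequence[nx.Graph],
    node_merge_radius_nm: float = DEFAULT_NODE_MERGE_RADIUS_NM,
    resolution=(1.0, 1.0, 1.0),
    edge_support_min: int = 1,
) -> nx.Graph:
    """Fuse several annotators' skeleton graphs into one consensus graph.

    Vertices (node attribute ``position``, voxel coords) from distinct
    annotators within the merge radius collapse into consensus vertices at
    the contributing points' centroid; a consensus edge appears when at
    least ``edge_support_min`` annotators drew an edge between the merged
    endpoints.  Vertex metadata such as synapse ``polarity`` is resolved
    by majority vote, with ties mapped to ``"unknown"``.
    """
    graphs = list(annotator_graphs)
    if not graphs:
        raise EmptyInputError("at least one annotator graph is required")

    entries = []   # (annotator idx, vertex, position nm)
    for a, g in enumerate(graphs):
        pos = _positions_nm(g, resolution)
        for v in g.nodes:
            entries.append((a, v, pos[v]))
    if not entries:
        return nx.Graph()
    nm = np.asarray([e[2] for e in entries])
    labels = _single_linkage_labels(nm, node_merge_radius_nm)

    cluster_of: dict[tuple[int, object], int] = {}
    consensus = nx.Graph()
    for cid in np.unique(labels):
        idx = np.nonzero(labels == cid)[0]
        centroid = nm[idx].mean(axis=0)
        best: dict[int, tuple[float, int]] = {}
        for i in idx:
            a = entries[i][0]
            d = float(np.linalg.norm(nm[i] - centroid))
            if a not in best or d < best[a][0]:
                best[a] = (d, i)
        kept = [i for _, i in best.values()]
        pos_vox = nm[kept].mean(axis=0) / np.asarray(resolution, dtype=float)
        polarity = _majority_polarity(
            graphs[entries[i][0]].nodes[entries[i][1]].get("polarity") for i in kept
        )
        node_id = int(cid)
        consensus.add_node(
            node_id,
            position=tuple(float(v) for v in pos_vox),
            support=len(best),
            contributors=sorted({entries[i][0] for i in idx}),
        )
        if polarity is not None:
            consensus.nodes[node_id]["polarity"] = polarity
        for i in idx:
            cluster_of[(entries[i][0], entries[i][1])] = node_id

    edge_support: dict[tuple[int, int], set[int]] = defaultdict(set)
    for a, g in enumerate(graphs):
        for u, v in g.edges:
            cu, cv = cluster_of[(a, u)], cluster_of[(a, v)]
            if cu == cv:
                continue
            edge_support[(min(cu, cv), max(cu, cv))].add(a)
    for (cu, cv), supporters in edge_support.items():
        if len(supporters) >= edge_support_min:
            consensus.add_edge(cu, cv, support=len(supporters))
    return consensus


def _majority_polarity(values: Iterable[Optional[str]]) -> Optional[str]:
    counts = Counter(v for v in values if v is not None)
    if not counts:
        return None
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return "unknown"
    return top[0][0]


# ---------------------------------------------------------------------------
# Cross-volume stitching
# ---------------------------------------------------------------------------


def stitch_adjacent(
    fragments: Sequence[tuple[nx.Graph, BoundingBox]],
    overlap_boxes: Optional[Mapping[tuple[int, int], BoundingBox]] = None,
    merge_radius_nm: float = DEFAULT_NODE_MERGE_RADIUS_NM,
    resolution=(1.0, 1.0, 1.0),
) -> nx.Graph:
    """Stitch skeleton fragments from overlapping task volumes.

    Task volumes are designed to overlap by a margin so traces can be
    joined across box boundaries.  Vertices of different fragments that
    both lie inside a shared overlap region and within ``merge_radius_nm``
    of each other are identified (each vertex pairs with its nearest
    eligible counterpart); edges are unioned over the identification.
    Fragments whose boxes do not overlap are simply concatenated.
    """
    frags = list(fragments)
    if not frags:
        raise EmptyInputError("at least one fragment is required")

    parent: dict[tuple[int, object], tuple[int, object]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    pos_nm: dict[tuple[int, object], np.ndarray] = {}
    for i, (g, _box) in enumerate(frags):
        for v in g.nodes:
            key = (i, v)
            parent[key] = key
            pos_nm[key] = to_nm(np.asarray(g.nodes[v]["position"]), resolution)[0]

    for i in range(len(frags)):
        for j in range(i + 1, len(frags)):
            gi, bi = frags[i]
            gj, bj = frags[j]
            if overlap_boxes is not None:
                overlap = overlap_boxes.get((i, j)) or overlap_boxes.get((j, i))
            else:
                overlap = bi.intersect(bj)
            if overlap is None:
                continue
            vi = [v for v in gi.nodes if overlap.contains(gi.nodes[v]["position"])]
            vj = [v for v in gj.nodes if overlap.contains(gj.nodes[v]["position"])]
            if not vi or not vj:
                continue
            tree = cKDTree(np.asarray([pos_nm[(j, v)] for v in vj]))
            for v in vi:
                dist, k = tree.query(pos_nm[(i, v)], distance_upper_bound=merge_radius_nm)
                if np.isfinite(dist):
                    union((i, v), (j, vj[k]))

    groups: dict[tuple[int, object], list[tuple[int, object]]] = defaultdict(list)
    for key in parent:
        groups[find(key)].append(key)

    stitched = nx.Graph()
    node_of: dict[tuple[int, object], int] = {}
    for new_id, (_root, members) in enumerate(sorted(groups.items(), key=lambda kv: str(kv[0]))):
        centroid = np.mean([pos_nm[m] for m in members], axis=0)
        pos_vox = centroid / np.asarray(resolution, dtype=float)
        stitched.add_node(
            new_id,
            position=tuple(float(v) for v in pos_vox),
            members=sorted(str(m) for m in members),
        )
        for m in members:
            node_of[m] = new_id
    for i, (g, _box) in enumerate(frags):
        for u, v in g.edges:
            a, b = node_of[(i, u)], node_of[(i, v)]
            if a != b:
                stitched.add_edge(a, b)
    return stitched
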