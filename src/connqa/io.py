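"""Readers and writers for the toolkit's interchange formats.

Skeletons travel as SWC (whitespace-delimited ``id type x y z radius
parent``, ``#`` comments, parent ``-1`` for roots); keypoints, bounding
boxes, terminal assignments and connectome edgelists as headered CSV;
score reports and store records as JSON.  All round-trips are lossless
for positions (full float precision), ids and labels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError
from .fusion import ConsensusKeypoint, KeypointSet
from .sampling import BoundingBox
from .scoring import ScoreReport, TerminalAssignment


# ---------------------------------------------------------------------------
# SWC skeletons
# ---------------------------------------------------------------------------


def read_swc(path, resolution=(1.0, 1.0, 1.0)) -> nx.Graph:
    """Read an SWC skeleton into a tree graph.

    Node attributes: ``position`` (x, y, z), ``radius``, ``swc_type``.
    Edge attribute ``length_nm`` is the coordinate delta scaled per axis
    by ``resolution``.  Cyclic or dangling parent references raise a
    :class:`FormatError` naming the offending line.
    """
    res = np.asarray(resolution, dtype=float)
    g = nx.Graph()
    parents: dict[int, tuple[int, int]] = {}   # node -> (parent, line number)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 SWC columns, got {len(fields)}")
            try:
                nid = int(fields[0])
                stype = int(fields[1])
                x, y, z, radius = (float(v) for v in fields[2:6])
                parent = int(fields[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if nid in g:
                raise FormatError(f"{path}:{lineno}: duplicate node id {nid}")
            g.add_node(nid, position=(x, y, z), radius=radius, swc_type=stype)
            if parent != -1:
                parents[nid] = (parent, lineno)
    directed = nx.DiGraph()
    directed.add_nodes_from(g.nodes)
    for nid, (parent, lineno) in parents.items():
        if parent not in g:
            raise FormatError(f"{path}:{lineno}: parent {parent} of node {nid} does not exist")
        delta = (np.asarray(g.nodes[nid]["position"]) - np.asarray(g.nodes[parent]["position"])) * res
        g.add_edge(nid, parent, length_nm=float(np.linalg.norm(delta)))
        directed.add_edge(nid, parent)
    if not nx.is_directed_acyclic_graph(directed) or (len(g) and not nx.is_forest(g)):
        raise FormatError(f"{path}: parent references form a cycle")
    return g


def write_swc(graph: nx.Graph, path, comment: str = "") -> None:
    """Write a tree graph as SWC (one root per connected component)."""
    path = Path(path)
    if len(graph) and not nx.is_forest(graph):
        raise FormatError("write_swc requires an acyclic graph")
    order = {nid: i + 1 for i, nid in enumerate(sorted(graph.nodes, key=str))}
    parent_of: dict = {}
    for comp in nx.connected_components(graph):
        root = min(comp, key=lambda n: order[n])
        for child, parent in nx.bfs_predecessors(graph.subgraph(comp), root):
            parent_of[child] = parent
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for nid in sorted(graph.nodes, key=lambda n: order[n]):
            x, y, z = (float(v) for v in graph.nodes[nid]["position"])
            radius = float(graph.nodes[nid].get("radius", 1.0))
            stype = int(graph.nodes[nid].get("swc_type", 0))
            parent = order[parent_of[nid]] if nid in parent_of else -1
            fh.write(f"{order[nid]} {stype} {x!r} {y!r} {z!r} {radius!r} {parent}\n")


# ---------------------------------------------------------------------------
# Keypoint CSV
# ---------------------------------------------------------------------------


def write_keypoints_csv(
    sets: Union[KeypointSet, Sequence[KeypointSet], Sequence[ConsensusKeypoint]],
    path,
) -> None:
    """Write keypoint sets (or consensus keypoints) as x,y,z[,annotator|support] CSV."""
    if isinstance(sets, KeypointSet):
        sets = [sets]
    sets = list(sets)
    rows = []
    if sets and isinstance(sets[0], ConsensusKeypoint):
        for ck in sets:
            rows.append({
                "x": ck.position[0], "y": ck.position[1], "z": ck.position[2],
                "support": ck.support, "contributors": ";".join(ck.contributors),
            })
        columns = ["x", "y", "z", "support", "contributors"]
    else:
        for ks in sets:
            for p in ks.points:
                rows.append({"x": p[0], "y": p[1], "z": p[2], "annotator": ks.annotator})
        columns = ["x", "y", "z", "annotator"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_keypoints_csv(path) -> list[KeypointSet]:
    """Read a keypoint CSV into per-annotator sets.

    A missing coordinate column is a :class:`FormatError`; a file without
    an ``annotator`` column yields a single anonymous set.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "annotator" not in df.columns:
        return [KeypointSet(annotator="", points=df[["x", "y", "z"]].to_numpy(float))]
    return [
        KeypointSet(annotator=str(name), points=group[["x", "y", "z"]].to_numpy(float))
        for name, group in df.groupby("annotator", sort=True)
    ]


# ---------------------------------------------------------------------------
# Boxes, assignments, edgelists, reports
# ---------------------------------------------------------------------------


def write_boxes_csv(boxes: Sequence[BoundingBox], path) -> None:
    rows = [
        {"x0": b.origin[0], "y0": b.origin[1], "z0": b.origin[2],
         "sx": b.shape[0], "sy": b.shape[1], "sz": b.shape[2]}
        for b in boxes
    ]
    pd.DataFrame(rows, columns=["x0", "y0", "z0", "sx", "sy", "sz"]).to_csv(path, index=False)


def read_boxes_csv(path) -> list[BoundingBox]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        BoundingBox((r.x0, r.y0, r.z0), (r.sx, r.sy, r.sz))
        for r in df.itertuples(index=False)
    ]


def write_assignment_csv(assignment: TerminalAssignment, path) -> None:
    rows = [{"terminal_id": t, "cell_id": c} for t, c in sorted(assignment.cell_of.items())]
    pd.DataFrame(rows, columns=["terminal_id", "cell_id"]).to_csv(path, index=False)


def read_assignment_csv(path) -> TerminalAssignment:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("terminal_id", "cell_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return TerminalAssignment(cell_of=dict(zip(df.terminal_id.astype(str), df.cell_id.astype(str))))


def write_labels_csv(labels: Mapping, path) -> None:
    """Sidecar mapping skeleton vertices to test segment labels."""
    rows = [{"vertex_id": v, "test_label": lab} for v, lab in sorted(labels.items(), key=lambda kv: str(kv[0]))]
    pd.DataFrame(rows, columns=["vertex_id", "test_label"]).to_csv(path, index=False)


def read_labels_csv(path) -> dict:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("vertex_id", "test_label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return dict(zip(df.vertex_id, df.test_label.astype(str)))


def export_edgelist(synapses: Iterable, path) -> pd.DataFrame:
    """Aggregate synapses into a (pre_cell, post_cell, count) connectome edgelist.

    Accepts anything with ``pre_cell`` / ``post_cell`` attributes (e.g. a
    synthetic world's synapse list).  Rows are written in lexicographic
    order; the count column sums parallel synapses.
    """
    counts: dict[tuple[str, str], int] = {}
    for s in synapses:
        key = (str(s.pre_cell), str(s.post_cell))
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"pre_cell": k[0], "post_cell": k[1], "count": counts[k]}
        for k in sorted(counts)
    ]
    df = pd.DataFrame(rows, columns=["pre_cell", "post_cell", "count"])
    df.to_csv(path, index=False)
    return df


def write_synapses_csv(synapses: Iterable, path) -> None:
    rows = [
        {"x": s.position[0], "y": s.position[1], "z": s.position[2],
         "pre_cell": s.pre_cell, "post_cell": s.post_cell}
        for s in synapses
    ]
    pd.DataFrame(rows, columns=["x", "y", "z", "pre_cell", "post_cell"]).to_csv(path, index=False)


def write_score_report(report: ScoreReport, path=None) -> str:
    text = json.dumps(report.as_dict(), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text
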