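"""Synthetic connectome worlds for exercising the assessment workflow.

Real assessment inputs — expert keypoint sets, neurite skeletons, segment
assignment tables — come from human annotation of electron-microscopy
volumes.  This module fabricates statistically similar inputs with known
ground truth so that sampling, fusion and scoring can be tested end to
end without imagery:

* :func:`generate_world` grows one random-walk tree skeleton per cell
  inside a bounded extent and scatters synapses on the skeletons at a
  Poisson rate per cubic micrometer; each synapse contributes a
  presynaptic and a postsynaptic *terminal* to the truth assignment.
* :func:`simulate_keypoint_annotator` corrupts the truth synapse set with
  misses (false negatives), spurious points (false positives) and
  Gaussian position jitter, parameterized by an :class:`AnnotatorProfile`.
* :func:`inject_reconstruction_errors` applies merge and split events to
  the truth assignment, emulating the two canonical segmentation failure
  modes: a *merge* gives all terminals of one cell another cell's id, a
  *split* partitions one cell's terminals between two new ids.
* :func:`simulate_decisions` fabricates forced-choice yes/no/maybe
  streams from annotators of known accuracy.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigurationError, ValidationError
from .fusion import KeypointSet
from .sampling import BoundingBox
from .scoring import TerminalAssignment

DEFAULT_STEP_NM = 200.0     # skeleton random-walk step length
DEFAULT_BRANCHING = 0.03    # per-step probability of starting a side branch
DEFAULT_STEPS_PER_CELL = 150
DEFAULT_MIN_SEPARATION_NM = 500.0   # synapses have physical extent; no overlaps


@dataclass
class AnnotatorProfile:
    """Error model for one simulated annotator.

    ``fn_rate`` — probability of missing a true synapse; ``fp_rate`` —
    expected spurious points per true point in the task box;
    ``jitter_sigma_nm`` — isotropic Gaussian position noise;
    ``choice_accuracy`` — probability a forced-choice answer is correct;
    ``maybe_rate`` — probability of abstaining with "maybe".
    """

    fn_rate: float = 0.0
    fp_rate: float = 0.0
    jitter_sigma_nm: float = 0.0
    choice_accuracy: float = 1.0
    maybe_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.fn_rate <= 1.0:
            raise ValidationError("fn_rate must be in [0, 1]")
        if self.fp_rate < 0:
            raise ValidationError("fp_rate must be >= 0")
        if self.jitter_sigma_nm < 0:
            raise ValidationError("jitter_sigma_nm must be >= 0")
        if not 0.0 <= self.choice_accuracy <= 1.0:
            raise ValidationError("choice_accuracy must be in [0, 1]")
        if not 0.0 <= self.maybe_rate <= 1.0:
            raise ValidationError("maybe_rate must be in [0, 1]")


@dataclass
class Synapse:
    id: str
    position: tuple[float, float, float]   # voxel coords
    pre_cell: str
    post_cell: str


@dataclass
class SyntheticWorld:
    """Ground truth: skeletons, synapses and the terminal-to-cell table."""

    extent: BoundingBox
    resolution: tuple[float, float, float]
    skeletons: dict[str, nx.Graph]         # cell id -> tree with length_nm edges
    synapses: list[Synapse]
    truth_assignment: TerminalAssignment
    seed: int

    def synapse_positions(self) -> np.ndarray:
        if not self.synapses:
            return np.empty((0, 3))
        return np.asarray([s.position for s in self.synapses], dtype=float)

    def skeleton_length_nm(self, cell_id: str) -> float:
        g = self.skeletons[cell_id]
        return float(sum(d["length_nm"] for _, _, d in g.edges(data=True)))


def _grow_skeleton(
    extent: BoundingBox,
    resolution: np.ndarray,
    rng: np.random.Generator,
    step_nm: float,
    branching: float,
    n_steps: int,
) -> nx.Graph:
    """Biased random-walk tree in voxel coordinates, clipped to the extent.

    The walk keeps a persistent direction with Gaussian perturbation and
    reflects off the extent boundary; with probability ``branching`` a
    step also seeds a side branch continued later from that vertex.
    """
    lo = np.asarray(extent.origin, dtype=float)
    hi = np.asarray(extent.end, dtype=float) - 1e-6
    step_vox = step_nm / resolution

    g = nx.Graph()
    start = rng.uniform(lo, hi)
    g.add_node(0, position=tuple(float(v) for v in start))
    direction = _unit(rng.standard_normal(3))
    # stack of (parent vertex, direction) walks still to extend
    stack = [(0, direction, n_steps)]
    next_id = 1
    while stack:
        node, direction, budget = stack.pop()
        pos = np.asarray(g.nodes[node]["position"], dtype=float)
        while budget > 0 and next_id < n_steps:
            direction = _unit(0.8 * direction + 0.6 * rng.standard_normal(3))
            new = pos + direction * step_vox
            # reflect off the boundary, axis by axis
            for ax in range(3):
                if new[ax] < lo[ax] or new[ax] > hi[ax]:
                    direction[ax] = -direction[ax]
                    new[ax] = np.clip(new[ax], lo[ax], hi[ax])
            length = float(np.linalg.norm((new - pos) * resolution))
            g.add_node(next_id, position=tuple(float(v) for v in new))
            g.add_edge(node, next_id, length_nm=length)
            node, pos = next_id, new
            next_id += 1
            budget -= 1
            if rng.random() < branching:
                stack.append((node, _unit(rng.standard_normal(3)), budget // 2))
    return g


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def generate_world(
    extent: BoundingBox,
    resolution,
    n_cells: int,
    synapse_density_per_um3: float,
    branching: float = DEFAULT_BRANCHING,
    seed: int = 0,
    step_nm: float = DEFAULT_STEP_NM,
    steps_per_cell: int = DEFAULT_STEPS_PER_CELL,
    min_separation_nm: float = DEFAULT_MIN_SEPARATION_NM,
) -> SyntheticWorld:
    """Generate a ground-truth world of skeletons, synapses and terminals.

    The expected synapse count is ``density x extent volume in um^3``
    (Poisson distributed).  Each synapse sits on a uniformly chosen edge
    of its presynaptic cell's skeleton; the postsynaptic cell is a
    distinct uniformly chosen cell, so producing any synapses requires at
    least two cells.  Because synapses are physical structures, no two
    are placed within ``min_separation_nm`` of each other: a draw landing
    too close to an existing synapse is resampled (and, after repeated
    failures on a saturated skeleton, dropped).
    """
    if n_cells < 0:
        raise ConfigurationError("n_cells must be >= 0")
    if synapse_density_per_um3 < 0:
        raise ConfigurationError("synapse density must be >= 0")
    if n_cells == 0 and synapse_density_per_um3 > 0:
        raise ConfigurationError("cannot place synapses in a world with zero cells")

    rng = np.random.default_rng(seed)
    res = np.asarray(resolution, dtype=float)
    cells = [f"cell{i}" for i in range(n_cells)]
    skeletons = {
        c: _grow_skeleton(extent, res, rng, step_nm, branching, steps_per_cell)
        for c in cells
    }

    synapses: list[Synapse] = []
    cell_of: dict[str, str] = {}
    expected = synapse_density_per_um3 * extent.volume_um3(res)
    n_syn = int(rng.poisson(expected)) if expected > 0 else 0
    if n_syn > 0 and n_cells < 2:
        raise ConfigurationError("synapses need at least two cells (pre != post)")
    placed_nm: list[np.ndarray] = []
    for i in range(n_syn):
        pre = cells[int(rng.integers(n_cells))]
        post = cells[int(rng.integers(n_cells - 1))]
        if post == pre:   # skip over pre in the cell list
            post = cells[n_cells - 1]
        edges = list(skeletons[pre].edges)
        pos = None
        for _attempt in range(100):
            u, v = edges[int(rng.integers(len(edges)))]
            t = float(rng.random())
            pu = np.asarray(skeletons[pre].nodes[u]["position"])
            pv = np.asarray(skeletons[pre].nodes[v]["position"])
            candidate = pu + t * (pv - pu)
            cand_nm = candidate * res
            if placed_nm and min_separation_nm > 0:
                d = np.linalg.norm(np.asarray(placed_nm) - cand_nm, axis=1)
                if float(d.min()) < min_separation_nm:
                    continue
            pos = tuple(float(x) for x in candidate)
            placed_nm.append(cand_nm)
            break
        if pos is None:    # skeleton saturated near this draw; drop it
            continue
        sid = f"syn{len(synapses)}"
        synapses.append(Synapse(id=sid, position=pos, pre_cell=pre, post_cell=post))
        cell_of[f"{sid}:pre"] = pre
        cell_of[f"{sid}:post"] = post

    return SyntheticWorld(
        extent=extent,
        resolution=tuple(float(r) for r in res),
        skeletons=skeletons,
        synapses=synapses,
        truth_assignment=TerminalAssignment(cell_of=cell_of),
        seed=seed,
    )


def simulate_keypoint_annotator(
    world: SyntheticWorld,
    profile: AnnotatorProfile,
    box: Optional[BoundingBox] = None,
    seed: int = 0,
    annotator: str = "sim",
) -> KeypointSet:
    """One simulated annotator's keypoint response for a task box.

    Each truth synapse inside the box is missed with probability
    ``fn_rate``; survivors are jittered by an isotropic Gaussian of
    ``jitter_sigma_nm`` (converted to voxels per axis, so jitter respects
    anisotropy); Poisson(``fp_rate`` x truth count) spurious points are
    placed uniformly in the box.
    """
    box = box or world.extent
    rng = np.random.default_rng(seed)
    res = np.asarray(world.resolution, dtype=float)

    truth = world.synapse_positions()
    in_box = np.asarray([box.contains(p) for p in truth], dtype=bool) if len(truth) else np.empty(0, bool)
    truth = truth[in_box] if len(truth) else truth

    keep = rng.random(len(truth)) >= profile.fn_rate
    points = truth[keep]
    if profile.jitter_sigma_nm > 0 and len(points):
        points = points + rng.normal(0.0, profile.jitter_sigma_nm, size=points.shape) / res

    n_fp = int(rng.poisson(profile.fp_rate * len(truth))) if len(truth) else 0
    if n_fp:
        lo = np.asarray(box.origin, dtype=float)
        hi = np.asarray(box.end, dtype=float)
        spurious = rng.uniform(lo, hi, size=(n_fp, 3))
        points = np.vstack([points, spurious]) if len(points) else spurious
    return KeypointSet(annotator=annotator, points=points)


def inject_reconstruction_errors(
    truth_assignment: TerminalAssignment,
    n_merge: int = 0,
    n_split: int = 0,
    seed: int = 0,
) -> TerminalAssignment:
    """Corrupt a perfect assignment with merge and split events.

    A merge relabels every terminal of one cell with another cell's id; a
    split partitions one multi-terminal cell's terminals into two fresh
    ids (uniform random nonempty bipartition).  Events model independent
    reconstruction errors, so each cell participates in at most one
    event: merge victim pairs are drawn uniformly without replacement,
    and split victims come from the remaining multi-terminal cells.  For
    a fixed seed the first ``k`` events of a larger request coincide with
    a ``k``-event request, so growing ``n_merge``/``n_split`` traces a
    trajectory of strictly accumulating damage.
    """
    if n_merge < 0 or n_split < 0:
        raise ConfigurationError("event counts must be >= 0")
    rng = np.random.default_rng(seed)
    cell_of = dict(truth_assignment.cell_of)
    by_cell: dict[str, list[str]] = {}
    for term, cell in cell_of.items():
        by_cell.setdefault(cell, []).append(term)
    cells = sorted(by_cell)
    shuffled = [cells[i] for i in rng.permutation(len(cells))]

    if 2 * n_merge > len(shuffled):
        raise ConfigurationError(
            f"{n_merge} merges need {2 * n_merge} distinct cells, have {len(shuffled)}"
        )
    merge_pairs = [(shuffled[2 * i], shuffled[2 * i + 1]) for i in range(n_merge)]
    # split victims are taken from the opposite end of the shuffle so the
    # two selections stay disjoint as either count grows
    candidates = [c for c in reversed(shuffled[2 * n_merge:]) if len(by_cell[c]) >= 2]
    if len(candidates) < n_split:
        raise ConfigurationError(
            f"{n_split} splits need that many spare multi-terminal cells, "
            f"have {len(candidates)}"
        )
    split_cells = candidates[:n_split]

    for victim, receiver in merge_pairs:
        for term in by_cell[victim]:
            cell_of[term] = receiver
    for cell in split_cells:
        terms = sorted(by_cell[cell])
        # per-cell stream: the bipartition depends only on (seed, cell)
        sub = np.random.default_rng([seed, cells.index(cell)])
        while True:
            side = sub.random(len(terms)) < 0.5
            if 0 < side.sum() < len(terms):
                break
        for term, s in zip(terms, side):
            cell_of[term] = f"{cell}.split{'a' if s else 'b'}"
    return TerminalAssignment(cell_of=cell_of)


def simulate_decisions(
    truth_verdicts: Sequence[str],
    profile: AnnotatorProfile,
    n_annotators: int,
    seed: int = 0,
) -> list[list[str]]:
    """Simulated forced-choice votes: one list of verdicts per item.

    Each annotator abstains with probability ``maybe_rate``; otherwise
    answers the true verdict with probability ``choice_accuracy`` and the
    opposite verdict with the complement.
    """
    rng = np.random.default_rng(seed)
    flip = {"yes": "no", "no": "yes"}
    stream: list[list[str]] = []
    for truth in truth_verdicts:
        if truth not in flip:
            raise ValidationError(f"truth verdict must be 'yes' or 'no', got {truth!r}")
        item = []
        for _ in range(n_annotators):
            if rng.random() < profile.maybe_rate:
                item.append("maybe")
            elif rng.random() < profile.choice_accuracy:
                item.append(truth)
            else:
                item.append(flip[truth])
        stream.append(item)
    return stream
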