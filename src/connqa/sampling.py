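"""Subvolume sampling for assessment tasks.

Assessment of a black-box reconstruction proceeds by drawing many small
boxes from the dataset extent, annotating each densely, and scoring the
annotations.  Synapse-assessment boxes are 5x5x5 um, neurite tracing uses
12x12x12 um (axon) and 7x7x7 um (dendrite) boxes around a 1x1x1 um seed
volume; :func:`um_to_voxels` converts these physical sizes to voxel shapes
at the volume's resolution.  Sampling is uniform or weighted by a scalar
field over a coarse grid of candidate origins, keeps every box inside a
padded extent, and is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    GeometryError,
    ValidationError,
)

DEFAULT_MIN_SYNAPSES = 5       # boxes with fewer synapses are degenerate
DEFAULT_MAX_MASK_FRACTION = 0.5  # boxes masked beyond this are degenerate


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned box ``[origin, origin + shape)`` in voxels."""

    origin: tuple[int, int, int]
    shape: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", tuple(int(v) for v in self.origin))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if any(s <= 0 for s in self.shape):
            raise ValidationError(f"box shape must be positive, got {self.shape}")

    @property
    def end(self) -> tuple[int, int, int]:
        return tuple(o + s for o, s in zip(self.origin, self.shape))

    def contains(self, point: Sequence[float]) -> bool:
        return all(o <= p < e for p, o, e in zip(point, self.origin, self.end))

    def intersect(self, other: "BoundingBox") -> Optional["BoundingBox"]:
        lo = tuple(max(a, b) for a, b in zip(self.origin, other.origin))
        hi = tuple(min(a, b) for a, b in zip(self.end, other.end))
        if any(h <= l for l, h in zip(lo, hi)):
            return None
        return BoundingBox(lo, tuple(h - l for l, h in zip(lo, hi)))

    def volume_um3(self, resolution: Sequence[float]) -> float:
        """Physical volume in cubic micrometers given nm-per-voxel resolution."""
        nm3 = math.prod(s * r for s, r in zip(self.shape, resolution))
        return nm3 / 1e9


def um_to_voxels(size_um: float | Sequence[float], resolution: Sequence[float]) -> tuple[int, int, int]:
    """Convert a physical box size in um to a voxel shape, rounding up per axis.

    ``resolution`` is nm per voxel along (x, y, z); a scalar ``size_um``
    means a cube of that side length.
    """
    if np.isscalar(size_um):
        size_um = (size_um,) * 3
    return tuple(
        max(1, math.ceil(s * 1000.0 / r)) for s, r in zip(size_um, resolution)
    )


@dataclass
class SamplingPlan:
    """How to draw assessment boxes from an extent.

    ``padding`` keeps boxes away from the dataset edges; ``strategy`` is
    ``uniform`` or ``weighted`` (``weight_field`` maps a candidate origin's
    box center to a non-negative weight, discretized on a coarse grid of
    pitch ``grid_pitch``, defaulting to half the box shape).
    """

    extent: BoundingBox
    box_shape: tuple[int, int, int]
    n_boxes: int
    padding: tuple[int, int, int] = (0, 0, 0)
    strategy: str = "uniform"
    weight_field: Optional[Callable[[np.ndarray], float]] = None
    grid_pitch: Optional[tuple[int, int, int]] = None
    seed: int = 0

    def __post_init__(self):
        self.box_shape = tuple(int(v) for v in self.box_shape)
        self.padding = tuple(int(v) for v in self.padding)
        if self.n_boxes < 0:
            raise ValidationError("n_boxes must be >= 0")
        if self.strategy not in ("uniform", "weighted"):
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if any(b + 2 * p > e for b, p, e in zip(self.box_shape, self.padding, self.extent.shape)):
            raise GeometryError(
                f"box {self.box_shape} with padding {self.padding} does not fit "
                f"inside extent {self.extent.shape}"
            )

    def origin_range(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        """Inclusive low / exclusive high candidate-origin bounds per axis."""
        lo = tuple(o + p for o, p in zip(self.extent.origin, self.padding))
        hi = tuple(
            o + e - p - b + 1
            for o, e, p, b in zip(self.extent.origin, self.extent.shape, self.padding, self.box_shape)
        )
        return lo, hi


def sample_boxes(plan: SamplingPlan) -> list[BoundingBox]:
    """Draw ``plan.n_boxes`` boxes (with replacement) from the padded extent.

    Uniform strategy: every admissible integer origin is equally likely.
    Weighted strategy: candidate origins on a coarse grid are drawn with
    probability proportional to ``weight_field`` at the box center.
    """
    rng = np.random.default_rng(plan.seed)
    lo, hi = plan.origin_range()
    if plan.n_boxes == 0:
        return []
    if plan.strategy == "uniform":
        origins = np.stack(
            [rng.integers(l, h, size=plan.n_boxes) for l, h in zip(lo, hi)], axis=1
        )
    else:
        if plan.weight_field is None:
            raise ValidationError("weighted strategy requires weight_field")
        pitch = plan.grid_pitch or tuple(max(1, b // 2) for b in plan.box_shape)
        axes = [np.arange(l, h, p) for l, h, p in zip(lo, hi, pitch)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        centers = grid + np.asarray(plan.box_shape) / 2.0
        weights = np.asarray([float(plan.weight_field(c)) for c in centers])
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValidationError("weight_field must be non-negative with positive mass")
        idx = rng.choice(len(grid), size=plan.n_boxes, p=weights / weights.sum())
        origins = grid[idx]
    return [BoundingBox(tuple(int(v) for v in o), plan.box_shape) for o in origins]


def filter_degenerate(
    boxes_with_annotations: Sequence[tuple],
    min_count: int = DEFAULT_MIN_SYNAPSES,
    max_mask_fraction: float = DEFAULT_MAX_MASK_FRACTION,
) -> tuple[list, list[tuple]]:
    """Drop degenerate assessment boxes; report why each rejection happened.

    Each entry is ``(box, synapse_count, mask_fraction)``.  A box is kept
    when its synapse count is at least ``min_count`` AND its masked-voxel
    fraction is at most ``max_mask_fraction``.  Returns ``(kept, log)``
    where ``log`` lists ``(entry, reason)`` for every rejection.
    """
    kept, log = [], []
    for entry in boxes_with_annotations:
        _box, count, mask_fraction = entry
        if not (0.0 <= mask_fraction <= 1.0):
            raise ValidationError(f"mask fraction {mask_fraction} outside [0, 1]")
        reasons = []
        if count < min_count:
            reasons.append(f"synapse count {count} less than {min_count}")
        if mask_fraction > max_mask_fraction:
            reasons.append(f"masked fraction {mask_fraction:.3f} exceeds {max_mask_fraction}")
        if reasons:
            log.append((entry, "; ".join(reasons)))
        else:
            kept.append(entry)
    return kept, log


def pick_seed_synapse(expert_keypoints, rng_seed: int):
    """Choose one seed synapse uniformly at random from an expert point set."""
    points = list(expert_keypoints)
    if not points:
        raise EmptyInputError("cannot pick a seed synapse from an empty keypoint set")
    rng = np.random.default_rng(rng_seed)
    return points[int(rng.integers(len(points)))]
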