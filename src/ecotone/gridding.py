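"""Belt/subplot gridding and subplot summary statistics.

The transect is partitioned into elevational belts (strips perpendicular
to the slope) that are subdivided into square subplots.  Subplot canopy
height is the height of the tallest individual strictly taller than the
seedling cutoff, or NA if there is none.  Subplot statistics are then
aggregated into belt-wise data vectors: ``Max_H(y)`` (highest subplot
canopy height per belt) and ``Max2_H(y)`` (second-highest), the raw
material for the abruptness metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import TransectSpec, TreeRecord

#: Belt-level fill value for Max_H / Max2_H when a belt has no (or no
#: second) subplot with an individual above the seedling cutoff.
EMPTY_BELT_VALUE = 0.0


@dataclass
class SubplotStats:
    """Summary statistics of one subplot."""

    belt_index: int
    subplot_index: int
    canopy_height: Optional[float]  # None (NA) iff no individual > cutoff
    n_individuals: int
    mean_cover: Optional[float] = None  # filled by the discreteness stage


@dataclass
class BeltVector:
    """A per-belt statistic vector, index 1 (bottom) to n_belts (top)."""

    values: np.ndarray
    label: str
    belt_midpoints: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.belt_midpoints = np.asarray(self.belt_midpoints, dtype=float)
        if self.values.shape != self.belt_midpoints.shape:
            raise ValueError("values and belt_midpoints must have equal length")

    def __len__(self) -> int:
        return len(self.values)


def grid_trees(
    trees: Sequence[TreeRecord], spec: TransectSpec
) -> dict[tuple[int, int], list[TreeRecord]]:
    """Assign every in-bounds tree to its (belt, subplot) cell.

    All cells are present in the returned mapping, empty ones with an
    empty list.  Belt/subplot intervals are half-open except at the top
    and far edges, so each tree lands in exactly one cell.
    """
    cells: dict[tuple[int, int], list[TreeRecord]] = {
        (b, s): []
        for b in range(1, spec.n_belts + 1)
        for s in range(1, spec.subplots_per_belt + 1)
    }
    for t in trees:
        if 0 <= t.y <= spec.length and 0 <= t.x <= spec.width:
            cells[(spec.belt_of(t.y), spec.subplot_of(t.x))].append(t)
    return cells


def subplot_canopy_heights(
    gridded: Mapping[tuple[int, int], Sequence[TreeRecord]], spec: TransectSpec
) -> list[SubplotStats]:
    """Per-subplot canopy height and individual count.

    Only individuals strictly taller than ``spec.seedling_cutoff`` count;
    a subplot without any is reported with canopy height NA (None).
    """
    out = []
    for b in range(1, spec.n_belts + 1):
        for s in range(1, spec.subplots_per_belt + 1):
            heights = [
                t.height
                for t in gridded[(b, s)]
                if t.height > spec.seedling_cutoff
            ]
            out.append(
                SubplotStats(
                    belt_index=b,
                    subplot_index=s,
                    canopy_height=max(heights) if heights else None,
                    n_individuals=len(heights),
                )
            )
    return out


def _max_and_second(values: Sequence[float]) -> tuple[float, float]:
    """Top two of a multiset of subplot canopy heights, zero-filled.

    Ties count separately: two subplots sharing the tallest canopy give
    a second value equal to the first.
    """
    if not values:
        return EMPTY_BELT_VALUE, EMPTY_BELT_VALUE
    if len(values) == 1:
        return float(values[0]), EMPTY_BELT_VALUE
    top = sorted(values, reverse=True)
    return float(top[0]), float(top[1])


def belt_max_vectors(
    stats: Sequence[SubplotStats], spec: TransectSpec
) -> tuple[BeltVector, BeltVector]:
    """Aggregate subplot canopy heights into Max_H(y) and Max2_H(y).

    Max_H is 0 for a belt with no individual above the seedling cutoff;
    Max2_H is 0 when fewer than two subplots in the belt have one.  NA
    subplots are skipped, not zero-filled, when taking the maxima.
    """
    per_belt: dict[int, list[float]] = {b: [] for b in range(1, spec.n_belts + 1)}
    for st in stats:
        if st.canopy_height is not None:
            per_belt[st.belt_index].append(st.canopy_height)
    max_h = np.empty(spec.n_belts)
    max2_h = np.empty(spec.n_belts)
    for b in range(1, spec.n_belts + 1):
        max_h[b - 1], max2_h[b - 1] = _max_and_second(per_belt[b])
    mids = spec.belt_midpoints
    return (
        BeltVector(max_h, "Max_H", mids),
        BeltVector(max2_h, "Max2_H", mids),
    )


def belt_counts(stats: Sequence[SubplotStats], spec: TransectSpec) -> BeltVector:
    """Per-belt count of individuals above the seedling cutoff (diagnostic)."""
    counts = np.zeros(spec.n_belts)
    for st in stats:
        counts[st.belt_index - 1] += st.n_individuals
    return BeltVector(counts, "n_individuals", spec.belt_midpoints)


def belt_vectors_from_edges(
    trees: Sequence[TreeRecord],
    edges: Sequence[float],
    spec: TransectSpec,
) -> tuple[BeltVector, BeltVector]:
    """Max_H / Max2_H for arbitrary belt edges (used by the belt-shift scan).

    ``edges`` are increasing y boundaries from 0 to the transect length;
    belts may have unequal widths (partial belts at either end of a
    shifted grid are retained).  Subplots remain the across-slope columns
    of width ``spec.subplot_size`` intersected with each belt strip.
    """
    edges = np.asarray(edges, dtype=float)
    if edges[0] != 0 or not math.isclose(edges[-1], spec.length):
        raise ValueError("edges must span the transect from 0 to length")
    n_belts = len(edges) - 1
    ncol = spec.subplots_per_belt
    canopy: dict[tuple[int, int], float] = {}
    for t in trees:
        if t.height <= spec.seedling_cutoff:
            continue
        if not (0 <= t.y <= spec.length and 0 <= t.x <= spec.width):
            continue
        b = min(int(np.searchsorted(edges, t.y, side="right")), n_belts)
        b = max(b, 1)
        c = spec.subplot_of(t.x)
        key = (b, c)
        if t.height > canopy.get(key, -np.inf):
            canopy[key] = t.height
    max_h = np.zeros(n_belts)
    max2_h = np.zeros(n_belts)
    for b in range(1, n_belts + 1):
        vals = [canopy[(b, c)] for c in range(1, ncol + 1) if (b, c) in canopy]
        max_h[b - 1], max2_h[b - 1] = _max_and_second(vals)
    mids = (edges[:-1] + edges[1:]) / 2
    return (
        BeltVector(max_h, "Max_H", mids),
        BeltVector(max2_h, "Max2_H", mids),
    )
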