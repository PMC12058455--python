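"""Abruptness metrics from canopy-height belt vectors.

The pipeline per vector (Max_H and, independently, Max2_H):

1. *Truncation*: find the topmost belt ``y_t`` whose value exceeds the
   forest cutoff (3 m by default) and cap all lower belts at that value.
   This removes canopy-height variation *within* the forest so that the
   metrics respond only to the forest-to-alpine transition.
2. *Smoothing*: descending from the topmost belt down to ``y_t``,
   replace each value by its upslope neighbour if that neighbour is
   higher.  This fills canopy gaps that would otherwise mimic an abrupt
   decline.
3. *Differences*: successive-belt differences of the smoothed vector,
   optionally normalized by the transect-wide maximum of the raw vector.

The final metrics are the largest between-belt decline: ``a_abr`` /
``a_abr2`` in metres, ``n_abr`` / ``n_abr2`` dimensionless in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import NoForestError, TransectSpec, TreeRecord
from .gridding import BeltVector, belt_vectors_from_edges


def truncate(v: BeltVector, forest_cutoff: float) -> tuple[BeltVector, int]:
    """Cap all belts at/below the truncation belt at its value.

    The truncation belt ``y_t`` (1-based) is the topmost belt whose value
    strictly exceeds ``forest_cutoff``; every belt above it is at or
    below the cutoff.  Values above ``y_t`` are left unchanged.

    Raises
    ------
    NoForestError
        If no belt exceeds the cutoff (metrics undefined).
    """
    vals = v.values
    above = np.nonzero(vals > forest_cutoff)[0]
    if len(above) == 0:
        raise NoForestError(
            f"no belt of {v.label} exceeds the forest cutoff {forest_cutoff} m"
        )
    yt0 = int(above[-1])  # 0-based index of the truncation belt
    out = vals.copy()
    out[: yt0 + 1] = vals[yt0]
    return BeltVector(out, f"t{v.label}", v.belt_midpoints), yt0 + 1


def smooth(tv: BeltVector, y_t: int) -> BeltVector:
    """Fill canopy gaps by the descending upslope-neighbour replacement.

    For belts from ``n_belts - 1`` down to ``y_t + 1`` (processed in that
    order), the value becomes the maximum of itself and its upslope
    neighbour.  Belts at or below ``y_t`` and the topmost belt are
    unchanged.
    """
    out = tv.values.copy()
    n = len(out)
    yt0 = y_t - 1
    for i in range(n - 2, yt0, -1):
        if out[i + 1] > out[i]:
            out[i] = out[i + 1]
    label = tv.label[1:] if tv.label.startswith("t") else tv.label
    return BeltVector(out, f"s{label}", tv.belt_midpoints)


@dataclass
class AbruptnessResult:
    """The four abruptness metrics with all intermediate vectors.

    Metrics derived from Max2_H are ``None`` when Max2_H carries no
    signal (all-zero, or never above the forest cutoff).  ``argmax_belt``
    maps each defined metric to the (lowest, on ties) belt index y at
    which the decline from belt y to y+1 is largest.
    """

    y_t: int
    t_max_h: BeltVector
    s_max_h: BeltVector
    delta: np.ndarray
    ndelta: np.ndarray
    a_abr: float
    n_abr: float
    y_t2: Optional[int] = None
    t_max2_h: Optional[BeltVector] = None
    s_max2_h: Optional[BeltVector] = None
    delta2: Optional[np.ndarray] = None
    ndelta2: Optional[np.ndarray] = None
    a_abr2: Optional[float] = None
    n_abr2: Optional[float] = None
    argmax_belt: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def metric_values(self) -> dict[str, Optional[float]]:
        return {
            "a_abr": self.a_abr,
            "a_abr2": self.a_abr2,
            "n_abr": self.n_abr,
            "n_abr2": self.n_abr2,
        }


def _vector_pipeline(
    v: BeltVector, forest_cutoff: float
) -> tuple[BeltVector, BeltVector, np.ndarray, np.ndarray, int, float, float, int]:
    """Truncate, smooth and difference one vector; return all stages."""
    tv, y_t = truncate(v, forest_cutoff)
    sv = smooth(tv, y_t)
    delta = np.diff(sv.values)  # delta[y-1] = s(y+1) - s(y), y = 1..n-1
    denom = float(np.max(v.values))  # raw, pre-truncation maximum
    ndelta = delta / denom
    i_min = int(np.argmin(delta))  # lowest belt index on ties
    a = float(-delta[i_min])
    n = float(-ndelta[i_min])
    return tv, sv, delta, ndelta, y_t, a, n, i_min + 1


def abruptness_metrics(
    max_h: BeltVector,
    max2_h: Optional[BeltVector],
    spec: TransectSpec,
    forest_cutoff: Optional[float] = None,
) -> AbruptnessResult:
    """Compute the four abruptness metrics from Max_H and Max2_H.

    Truncation belts are found independently per vector.  Normalization
    divides each difference vector by the transect-wide maximum of its
    own *raw* vector, so ``n_abr = a_abr / max(Max_H)`` holds exactly.

    Raises
    ------
    NoForestError
        If Max_H never exceeds the forest cutoff.  A Max2_H that never
        does only leaves ``a_abr2`` / ``n_abr2`` undefined.
    """
    cutoff = spec.forest_cutoff if forest_cutoff is None else forest_cutoff
    tv, sv, delta, ndelta, y_t, a_abr, n_abr, arg1 = _vector_pipeline(max_h, cutoff)

    res = AbruptnessResult(
        y_t=y_t,
        t_max_h=tv,
        s_max_h=sv,
        delta=delta,
        ndelta=ndelta,
        a_abr=a_abr,
        n_abr=n_abr,
        argmax_belt={"a_abr": arg1, "n_abr": arg1},
    )
    # internal consistency: the normalized metric is the absolute metric
    # rescaled by the raw transect maximum
    assert abs(n_abr - a_abr / np.max(max_h.values)) < 1e-12

    if sv.values[-1] > 0:
        res.warnings.append(
            "edge-truncated ecotone: canopy persists into the top belt; "
            "part of the decline may lie beyond the transect"
        )

    if max2_h is not None and np.max(max2_h.values) > 0:
        try:
            tv2, sv2, d2, nd2, y_t2, a2, n2, arg2 = _vector_pipeline(max2_h, cutoff)
        except NoForestError:
            res.warnings.append(
                "Max2_H never exceeds the forest cutoff; a_abr2/n_abr2 undefined"
            )
        else:
            res.y_t2 = y_t2
            res.t_max2_h = tv2
            res.s_max2_h = sv2
            res.delta2 = d2
            res.ndelta2 = nd2
            res.a_abr2 = a2
            res.n_abr2 = n2
            res.argmax_belt.update({"a_abr2": arg2, "n_abr2": arg2})
    elif max2_h is not None:
        res.warnings.append("Max2_H is all-zero; a_abr2/n_abr2 undefined")
    return res


@dataclass
class ShiftScanResult:
    """Abruptness recomputed over shifted belt grids, with dispersion."""

    offsets: list[float]
    results: list[AbruptnessResult]
    dispersion: dict[str, dict[str, float]]

    def to_records(self) -> list[dict]:
        rows = []
        for off, r in zip(self.offsets, self.results):
            for metric, value in r.metric_values().items():
                rows.append({"offset": off, "metric": metric, "value": value})
        return rows


def belt_shift_scan(
    trees: Sequence[TreeRecord],
    spec: TransectSpec,
    step: float = 1.0,
    forest_cutoff: Optional[float] = None,
) -> ShiftScanResult:
    """Recompute abruptness with belt origins shifted by multiples of ``step``.

    A decline concentrated in a single step of the canopy shows a large
    drop at every offset (low dispersion of ``a_abr``), whereas a steep
    but continuous decline is split between belts differently at each
    offset.  Partial belts created at either end of a shifted grid are
    retained.

    ``step`` must divide the belt width evenly.
    """
    n_off = spec.belt_width / step
    if abs(n_off - round(n_off)) > 1e-9 or round(n_off) < 1:
        raise ValueError("step must evenly divide the belt width")
    offsets = [k * step for k in range(round(n_off))]
    results = []
    for off in offsets:
        if off == 0:
            edges = np.arange(0, spec.length + spec.belt_width / 2, spec.belt_width)
        else:
            inner = np.arange(off, spec.length - 1e-9, spec.belt_width)
            edges = np.concatenate([[0.0], inner, [spec.length]])
        max_h, max2_h = belt_vectors_from_edges(trees, edges, spec)
        results.append(abruptness_metrics(max_h, max2_h, spec, forest_cutoff))
    dispersion = {}
    for metric in ("a_abr", "n_abr"):
        vals = [getattr(r, metric) for r in results]
        dispersion[metric] = {
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
            "range": float(np.max(vals) - np.min(vals)),
            "mean": float(np.mean(vals)),
        }
    return ShiftScanResult(offsets=offsets, results=results, dispersion=dispersion)
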