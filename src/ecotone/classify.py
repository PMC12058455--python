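"""Categorical treeline forms from the continuous metrics.

Abruptness: each of the four metrics maps to gradual / intermediate /
abrupt via threshold cuts (absolute cuts are lowered by 1 m when a
krummholz belt is present, because krummholz compresses the canopy-height
range).  A consensus label summarizes the per-metric votes; directly
contradicting votes (abrupt vs. gradual) yield "conflicting", which in
practice calls for a manual assessment of the site.

Discreteness: a valid logistic fit with s at or above the cut is
discrete, below it diffuse.  A fitted forest cover below the minimum
forces diffuse (no discrete cover transition is possible at such low
cover); a transition midpoint outside the interpretable range, or a
failed fit, leaves the site unclassifiable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Union

from .core import ClassificationThresholds
from .abruptness import AbruptnessResult
from .discreteness import DiscretenessResult, FitStatus

GRADUAL = "gradual"
INTERMEDIATE = "intermediate"
ABRUPT = "abrupt"
UNDEFINED = "undefined"
CONFLICTING = "conflicting"

DISCRETE = "discrete"
DIFFUSE = "diffuse"
UNCLASSIFIABLE = "unclassifiable"


@dataclass
class AbruptnessClass:
    by_metric: dict[str, str]
    consensus: str
    krummholz_present: bool
    boundary_hits: list[str]


@dataclass
class DiscretenessClass:
    label: str
    reason: str


def _cut_label(
    value: float, gradual_below: float, abrupt_above: float
) -> tuple[str, bool]:
    """Label one metric; also report whether it sits exactly on a cut."""
    on_boundary = value == gradual_below or value == abrupt_above
    if value < gradual_below:
        return GRADUAL, on_boundary
    if value > abrupt_above:
        return ABRUPT, on_boundary
    return INTERMEDIATE, on_boundary


def classify_abruptness(
    result: Union[AbruptnessResult, Mapping[str, Optional[float]]],
    krummholz_present: bool,
    thresholds: Optional[ClassificationThresholds] = None,
) -> AbruptnessClass:
    """Per-metric and consensus abruptness labels.

    ``result`` may be an :class:`AbruptnessResult` or a plain mapping of
    metric names (``a_abr``, ``a_abr2``, ``n_abr``, ``n_abr2``) to values
    (None for undefined metrics, which are excluded from the consensus).
    Cuts are strict inequalities: a value exactly at a cut is
    intermediate and flagged as a boundary hit.
    """
    th = thresholds or ClassificationThresholds()
    values = (
        result.metric_values()
        if isinstance(result, AbruptnessResult)
        else dict(result)
    )
    red = th.krummholz_reduction_m if krummholz_present else 0.0
    cuts = {
        "a_abr": (th.a_abr_gradual_m - red, th.a_abr_abrupt_m - red),
        "a_abr2": (th.a_abr2_gradual_m - red, th.a_abr_abrupt_m - red),
        "n_abr": (th.n_abr_gradual, th.n_abr_abrupt),
        "n_abr2": (th.n_abr_gradual, th.n_abr_abrupt),
    }
    by_metric: dict[str, str] = {}
    boundary_hits: list[str] = []
    for metric, (lo, hi) in cuts.items():
        v = values.get(metric)
        if v is None:
            by_metric[metric] = UNDEFINED
            continue
        label, on_boundary = _cut_label(float(v), lo, hi)
        by_metric[metric] = label
        if on_boundary:
            boundary_hits.append(metric)

    votes = [l for l in by_metric.values() if l != UNDEFINED]
    if not votes:
        consensus = UNDEFINED
    elif ABRUPT in votes and GRADUAL in votes:
        consensus = CONFLICTING
    else:
        counts = Counter(votes)
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            consensus = INTERMEDIATE  # tie between adjacent labels
        else:
            consensus = top[0][0]
    return AbruptnessClass(
        by_metric=by_metric,
        consensus=consensus,
        krummholz_present=krummholz_present,
        boundary_hits=boundary_hits,
    )


def classify_discreteness(
    result: DiscretenessResult,
    thresholds: Optional[ClassificationThresholds] = None,
) -> DiscretenessClass:
    """Discrete / diffuse / unclassifiable from the logistic fit.

    The steepness cut is inclusive (s exactly at the cut is discrete).
    """
    th = thresholds or ClassificationThresholds()
    if result.status == FitStatus.low_forest_cover:
        return DiscretenessClass(
            label=DIFFUSE,
            reason=(
                f"C_max = {result.c_max:.3g} < {th.c_max_min}: no discrete "
                "cover transition is possible at such low forest cover"
            ),
        )
    if result.status != FitStatus.ok:
        return DiscretenessClass(
            label=UNCLASSIFIABLE,
            reason=result.message or result.status.value,
        )
    if result.s >= th.s_discrete:
        return DiscretenessClass(
            label=DISCRETE,
            reason=f"s = {result.s:.3g} >= {th.s_discrete}",
        )
    return DiscretenessClass(
        label=DIFFUSE,
        reason=f"s = {result.s:.3g} < {th.s_discrete}",
    )
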