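# Methods

This note documents the models, conventions, and numerical choices
behind the package, in the order of the pipeline.

## Gridding and canopy-height vectors

The transect (length L along the elevational gradient, width W across
the slope) is partitioned into `n_b = L / belt_width` elevational belts
subdivided into square subplots (`subplot_size`, default 5 m). Both
divisions must be exact; the constructor rejects geometries that do not
tile. Belts and subplots are half-open intervals `[low, high)` except
at the top/far edge, which is closed — every in-bounds tree belongs to
exactly one cell. Belt 1 is the transect bottom; the belt coordinate is
its midpoint `(i − ½) · belt_width`.

Subplot canopy height is the height of the tallest individual *strictly*
taller than the seedling cutoff (0.5 m), or NA when there is none. The
strict inequality is a deliberate, testable convention (an exactly
0.5-m individual does not count). Belt-wise, `Max_H(y)` is the highest
subplot canopy height (0 if the belt has no individual above the
cutoff) and `Max2_H(y)` the second-highest subplot value (0 if fewer
than two subplots are occupied). NA subplots are skipped — not
zero-filled — when taking these maxima; zero-filling happens only at
the belt level by the two rules above. When two subplots tie for the
highest canopy, `Max2_H = Max_H` (the second element of the descending
multiset). With 12 subplots per belt, `Max2_H` coincides with the
nearest-rank 92nd percentile of the belt's subplot values, which the
test suite asserts.

Using maxima rather than means is intentional: a single tall "outpost"
individual near the upper ecotone border demonstrates the belt's growth
potential and should not be averaged away. `Max2_H` and its derived
metrics deliberately remove that influence, giving a robustness
counterpart.

## Abruptness

Per vector, truncation finds the topmost belt `y_t` with value
strictly above the forest cutoff (3 m) and caps all lower belts at
`v(y_t)`. A belt exactly at 3 m never qualifies as forest, so `y_t` is
simply the topmost belt with `v > 3 m` — this makes the definition
total (the boundary case "exactly 3 m above `y_t`" is otherwise
unconstrained). If no belt exceeds the cutoff the transect has no
forest and the abruptness metrics are reported undefined
(`NoForestError`). `y_t` is found independently for `Max_H` and
`Max2_H`.

Smoothing walks from belt `n_b − 1` down to `y_t + 1`, replacing each
value by its upslope neighbour when that is higher. It never decreases
a value, never touches belts ≤ `y_t`, and leaves the topmost belt
unchanged; an uphill-non-increasing vector is a fixed point.

The difference vector is `δ(y) = s(y+1) − s(y)` for `y = 1 … n_b − 1`
on the smoothed vector; the normalized version divides by the maximum
of the *raw pre-truncation* vector over the whole transect (`max Max_H`
for `n_abr`, `max Max2_H` for `n_abr2` — "the largest overall canopy
height", not the truncated plateau). The metrics are `a_abr = −min δ`
(and analogues); the smoothed vector is non-increasing uphill by
construction, so `a_abr ≥ 0` and `n_abr ∈ [0, 1]` always, and
`n_abr = a_abr / max(Max_H)` holds as an exact identity (asserted at
run time). Ties in the minimum report the lowest belt index; only the
reported location, never the metric value, depends on this. If the
smoothed vector is still positive at the top belt, part of the decline
may lie beyond the transect; the result then carries an
"edge-truncated ecotone" warning rather than a silent metric.

The belt-shift scan recomputes the whole pipeline with belt origins
offset by 0, step, 2·step, … < belt_width (default 1-m steps). Partial
belts at either end of a shifted grid are retained. A canopy decline
concentrated in a single step shows the full drop at every offset (low
dispersion of `a_abr`); a steep but continuous decline is split
between belts differently at each offset (high dispersion). The scan
reports per-offset metrics plus min/max/range/mean.

No function is fitted to the height vectors: canopy height commonly
keeps increasing below the ecotone, which a sigmoid cannot represent;
the difference-based metrics need no assumption about the ecotone's
lower border.

## Cover and discreteness

Cover is the union of circular crown disks — overlap counts once —
projected on square cells (1 m default). Each cell's covered fraction
is estimated on a deterministic `supersample × supersample` subgrid of
cell-center points (default 10 × 10, i.e. 1 % of cell area per
subpoint); a subpoint is covered iff it lies in at least one disk.
This is exact enough (a single interior 4-m-radius disk reproduces
π r² to ≈ 0.05 %, asserted at 2 % in the tests), bit-reproducible, and
monotone under tree addition. Crowns are clipped at the transect
boundary; cover near edges is therefore biased slightly low, exactly
as in field data where neighbours outside the plot are unrecorded.
Missing crown diameters are filled as `crown_ratio × height`
(default ½). All records with a crown contribute to cover, including
sub-seedling individuals: cover is physiognomic, not demographic.

Subplot mean cover (25 cells at defaults) is fitted along y, one point
per subplot at its belt midpoint — so belts with more subplots carry
proportionally more weight — with
`C(y) = C_max / (1 + exp(s (y − y_l)))`, `s ≥ 0` (cover must decline
uphill). The fit is nonlinear least squares (scipy's trust-region
reflective solver, a damped Gauss–Newton family method) with tight
tolerances and a small multi-start: `C_max⁰` = mean cover of the bottom
two belts, `y_l⁰` = first crossing of half that value on an
uphill-monotone envelope of the per-belt profile (fallback: transect
midpoint), and `s⁰ ∈ {0.1, 0.02, 0.05, 0.2, 0.5}`; the lowest-cost
converged solution wins. `C_max` is *not* capped at 1 — data points
are proportions but the fitted plateau may legitimately exceed 1 when
the true plateau lies below the transect. The logistic is evaluated
via the numerically safe `expit`.

Validity rules, applied in this order (first match wins):

1. non-convergence, or `s` pinned at 0 → `fit_failed`;
2. `C_max < 0.4` → `low_forest_cover` (classification: diffuse — at
   such sparse forest no discrete cover transition is possible, and
   `y_l` is too poorly identified for the midpoint rules to mean much,
   which is why this rule precedes them);
3. `y_l ≤ 5 m` → `midpoint_below_margin`; `y_l > L` →
   `midpoint_above_transect` (classification: unclassifiable — most of
   the transition lies outside the sampled area).

Otherwise the label is discrete when `s ≥ 0.2` and diffuse below. The
cut is inclusive, and a fit exactly at a cut is flagged in the report.
At the cut, the 80 %-to-20 % (of `C_max`) transition spans
`2 ln 4 / s ≈ 13.9 m` — about three 5-m belts.

## Classification thresholds

Abruptness cuts (strict inequalities; values exactly at a cut are
intermediate and flagged): gradual below 2 m (`a_abr`) / 1.5 m
(`a_abr2`) / 0.25 (`n_abr`, `n_abr2`); abrupt above 3 m (`a_abr`,
`a_abr2`) / 0.40. With a krummholz belt present, *all absolute* cuts
drop by 1 m (normalized cuts are unchanged); the reduction is applied
uniformly, including to the `a_abr2` gradual cut, as a single
interpretation of "reduce the criteria by 1 m". Krummholz presence is
taken from the input flag (any record marked `krummholz`) or an
explicit override — no automatic krummholz detection is attempted.

The consensus label is the majority of the defined per-metric labels,
with two special cases: a direct contradiction (one metric abrupt,
another gradual) yields `conflicting` — such sites need manual
assessment — and ties between adjacent labels resolve to
`intermediate`. Undefined metrics (e.g. `Max2_H` all zero) are
excluded from the vote. All cuts live in `ClassificationThresholds`,
so the conventions are defaults, not constants.

## Synthetic generator

The generator emulates idealized end-state ecotones, not their
dynamics: canopy height follows either a linear decline (`h_max` at
y = 0 to 0 at `y_top`) or a step (`h_max` below `y_step`, a residual
height — constrained below the seedling cutoff — above); target cover
follows the logistic with true parameters `(C_max, y_l, s)`. Trees are
placed by an inhomogeneous Poisson process sampled in 1-m strips with
intensity

`λ(y) = −ln(1 − C(y)) / (π E[r(y)²])`,

the Boolean-model inversion, so the *expected* union cover equals the
target despite crown overlap. `E[r²]` accounts for the multiplicative
height noise `H · (1 − noise · U)`, `U ~ Uniform(0, 1)` (default
noise = 0.1, a realistic ~10 % downward size scatter); crown diameter
is `crown_ratio × height`. Where the height profile approaches zero a
placement floor (0.3 m, below the seedling cutoff) keeps the intensity
finite; scenarios demanding more than `max_intensity` (10 trees/m²)
anywhere are rejected with a `ScenarioError` rather than silently
producing absurd densities. An optional krummholz belt caps heights in
a y-range and flags those records. Same scenario + seed → identical
pattern.

What the generator does *not* reproduce: spatial clustering or
inhibition (placement is completely random given λ), demography, crown
shapes other than circles, and cover contributions from outside the
transect (edge clipping). Passing recovery tests therefore shows the
metrics recover known gradients under realistic densities and noise —
not that they are robust to aggregation, disturbance mosaics, or
sinuous treelines, which real sites can add.

Preset scenarios couple the two axes the way the idealized forms do:
the gradual–discrete preset lets height reach shrub stature near the
discrete cover edge, and the abrupt presets put the cover midpoint at
or below the height step, so the cover transition is carried by
tree-stature individuals rather than by implausibly dense residual
vegetation.

## Problem sizes and observed performance

The validation studies use the standard 180 × 60 m transect (36 belts
× 12 subplots, ≈ 500–6000 trees per pattern, chosen to mirror a
realistic hillslope census). Steepness recovery runs
4 × 3 × 20 = 240 generate–rasterize–fit cycles and achieves median
relative error ≈ 0.10–0.15 per true `s`, with ≥ 90 % label agreement
away from the `s = 0.2` boundary; the known failure mode is
`C_max_true = 0.4` sitting exactly on the low-cover cut, where the
small edge-clipping bias of realized cover pushes some fits just below
0.4 and forces the diffuse label. Step recovery finds `a_abr` within
`[ΔH − 1, ΔH]` for steps of 4–8 m (the shortfall is exactly the height
noise of the tallest tree in the truncation belt). The full suite runs
in well under a minute on one core.

## Known limitations

- Abruptness is resolution-dependent by design: `a_abr = 2 m` means
  0.4 m height loss per meter with 5-m belts but 0.2 m/m with 10-m
  belts. Compare sites only at equal belt widths.
- A steep decline straddling a belt boundary is split between two
  belts and can halve `a_abr`; the belt-shift scan exists to diagnose
  exactly this.
- Sinuous or oblique treelines inflate the apparent transition width;
  the logistic fit assumes the edge is roughly perpendicular to y. No
  correction is applied.
- The consensus abruptness label is a convenience; contradictory
  metrics (`conflicting`) genuinely require expert judgement.
- Age is read if present but unused; no metric here consumes it.
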