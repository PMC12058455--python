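# treeline-ecotone

Quantification and classification of spatial patterns in alpine
treeline ecotones — the transition zone between closed upper-montane
forest and treeless alpine vegetation — from tree point-pattern data
(positions, heights, optional crown diameters) on a rectangular
hillslope transect.

Treeline ecotones are commonly described along two pattern axes, but
usually by eye. This package computes reproducible metrics for both:

- **Abruptness** (lateral view: how suddenly does canopy *height*
  decline?). The transect is divided into elevational belts (default
  5 m) and 5 × 5 m subplots. Per belt, `Max_H(y)` is the highest
  subplot canopy height (individuals > 0.5 m) and `Max2_H(y)` the
  second-highest. Each vector is *truncated* at the topmost belt `y_t`
  with `Max_H(y_t) > 3 m` (all lower belts capped at that value, which
  removes within-forest height variation) and *smoothed* top-down
  (each belt raised to its upslope neighbour if that is higher, which
  removes canopy gaps). The metrics are the largest decline between
  successive belts of the smoothed vector:

  `a_abr = −min δsMax_H(y)` (m), and normalized by the transect-wide
  raw maximum, `n_abr = a_abr / max Max_H(y)` ∈ [0, 1]; likewise
  `a_abr2`, `n_abr2` from `Max2_H`. Suggested cuts: gradual below
  `a_abr < 2 m` / `n_abr < 0.25`, abrupt above `a_abr > 3 m` /
  `n_abr > 0.40` (absolute cuts reduced by 1 m when a krummholz belt
  is present).

- **Discreteness** (top-down view: how suddenly does tree *cover*
  decline?). Cover is the union of circular crowns (crown diameter =
  height/2 where unmeasured) rasterized on 1 × 1 m cells, averaged per
  subplot, and fitted with the three-parameter logistic

  `C(y) = C_max / (1 + exp(s (y − y_l)))`.

  The steepness `s` (per m) is the discreteness metric: `s ≥ 0.2` is
  discrete, below is diffuse. Fits with `C_max < 0.4` are diffuse by
  definition (no discrete cover transition is possible at such low
  forest cover); fits whose midpoint `y_l` falls at the transect edges
  (`y_l ≤ 5 m` or beyond the top) are not interpretable.

A synthetic generator produces idealized ecotones (gradual/abrupt
height forms × discrete/diffuse logistic cover, optional krummholz
belt) with known ground truth via an inhomogeneous Poisson process, so
every metric can be validated by parameter recovery without field data.

## Worked example

Simulate the idealized abrupt–discrete form on a 180 × 60 m transect
and run the full pipeline on the resulting point pattern:

```sh
$ printf 'preset: abrupt_discrete\nseed: 11\n' > scenario.yaml
$ ecotone simulate scenario.yaml --out sim
wrote 1157 trees to sim/pattern.csv
$ ecotone metrics sim/pattern.csv --length 180 --width 60 --out out
abruptness: a_abr=7.95 m, n_abr=0.994 (abrupt); discreteness: s=0.4286 (discrete)
```

The scenario steps canopy height from 8 m down to sub-seedling stature
at y = 100 m, with a logistic cover decline (`C_max = 0.6`,
`y_l = 95 m`, `s = 0.4`). The pipeline recovers `a_abr = 7.95 m` — the
full 8-m canopy step, less only the height noise of the tallest tree
in the truncation belt — and `n_abr = 0.994`: essentially the whole
forest stature is lost in one 5-m belt, an unambiguously abrupt
treeline. The fitted steepness `s = 0.43 ≥ 0.2` classifies the forest
edge as discrete, with `C_max` and `y_l` recovered near their true
values. `out/report.json` carries all four abruptness metrics, the
fitted logistic parameters with validity status, per-metric and
consensus class labels, the thresholds used, and every intermediate
belt vector (also flattened to `out/belt_vectors.csv`, with the cover
raster in `out/cover_grid.csv`).

The same command works on field CSVs with columns
`x, y, height[, crown_diameter, growth_form, age]` (meters, y pointing
uphill). `--cover-grid` substitutes an externally derived cover raster
(e.g. from remote sensing) for crown rasterization; `--shift-scan`
re-estimates abruptness over belt grids shifted in 1-m steps to check
whether a detected step is robust to belt placement.

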