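"""End-to-end orchestration: gridding -> abruptness -> discreteness -> classes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .abruptness import AbruptnessResult, ShiftScanResult, abruptness_metrics, belt_shift_scan
from .classify import (
    AbruptnessClass,
    DiscretenessClass,
    classify_abruptness,
    classify_discreteness,
)
from .core import Config, GrowthForm, TransectSpec, TreeRecord
from .discreteness import (
    CoverGrid,
    DiscretenessResult,
    fit_cover_logistic,
    rasterize_cover,
    subplot_mean_cover,
)
from .gridding import belt_counts, belt_max_vectors, grid_trees, subplot_canopy_heights


@dataclass
class EcotoneAnalysis:
    """Everything one run computes, ready for reporting."""

    spec: TransectSpec
    config: Config
    abruptness: AbruptnessResult
    discreteness: DiscretenessResult
    abruptness_class: AbruptnessClass
    discreteness_class: DiscretenessClass
    cover_grid: CoverGrid
    subplot_cover: pd.DataFrame
    krummholz_present: bool
    shift_scan: Optional[ShiftScanResult] = None
    warnings: list = field(default_factory=list)
    max_h: Optional[np.ndarray] = None
    max2_h: Optional[np.ndarray] = None
    belt_n: Optional[np.ndarray] = None

    def belt_table(self) -> pd.DataFrame:
        """Flat per-belt table of all intermediate vectors."""
        a = self.abruptness
        n = len(a.s_max_h)
        cover_by_belt = (
            self.subplot_cover.groupby("belt_index")["mean_cover"].mean().to_numpy()
        )
        def _pad_delta(d):
            if d is None:
                return np.full(n, np.nan)
            return np.concatenate([d, [np.nan]])
        def _vec(v):
            return np.full(n, np.nan) if v is None else np.asarray(v, dtype=float)
        return pd.DataFrame(
            {
                "belt_index": np.arange(1, n + 1),
                "midpoint_y": a.s_max_h.belt_midpoints,
                "Max_H": _vec(self.max_h),
                "Max2_H": _vec(self.max2_h),
                "tMax_H": a.t_max_h.values,
                "sMax_H": a.s_max_h.values,
                "tMax2_H": _vec(None if a.t_max2_h is None else a.t_max2_h.values),
                "sMax2_H": _vec(None if a.s_max2_h is None else a.s_max2_h.values),
                "delta_Max_H": _pad_delta(a.delta),
                "delta_Max2_H": _pad_delta(a.delta2),
                "n_individuals": _vec(self.belt_n),
                "cover_mean": cover_by_belt,
            }
        )

    def to_report(self) -> dict:
        a = self.abruptness
        d = self.discreteness
        return {
            "tool": {"name": "treeline-ecotone", "version": __version__},
            "transect": {
                "length_m": self.spec.length,
                "width_m": self.spec.width,
                "belt_width_m": self.spec.belt_width,
                "subplot_size_m": self.spec.subplot_size,
                "cell_size_m": self.spec.cell_size,
                "seedling_cutoff_m": self.spec.seedling_cutoff,
                "forest_cutoff_m": self.spec.forest_cutoff,
                "n_belts": self.spec.n_belts,
                "subplots_per_belt": self.spec.subplots_per_belt,
            },
            "abruptness": {
                "a_abr": a.a_abr,
                "a_abr2": a.a_abr2,
                "n_abr": a.n_abr,
                "n_abr2": a.n_abr2,
                "y_t": a.y_t,
                "y_t2": a.y_t2,
                "argmax_belt": a.argmax_belt,
                "warnings": a.warnings,
            },
            "abruptness_class": {
                "by_metric": self.abruptness_class.by_metric,
                "consensus": self.abruptness_class.consensus,
                "krummholz_present": self.abruptness_class.krummholz_present,
                "boundary_hits": self.abruptness_class.boundary_hits,
            },
            "discreteness": {
                "C_max": d.c_max,
                "y_l": d.y_l,
                "s": d.s,
                "rss": d.rss,
                "converged": d.converged,
                "status": d.status.value,
                "interpretable": d.interpretable,
                "message": d.message,
                "n_points": d.n_points,
            },
            "discreteness_class": {
                "label": self.discreteness_class.label,
                "reason": self.discreteness_class.reason,
            },
            "thresholds": self.config.thresholds,
            "crown_ratio": self.config.crown_ratio,
            "shift_scan": (
                None
                if self.shift_scan is None
                else {
                    "offsets": self.shift_scan.offsets,
                    "dispersion": self.shift_scan.dispersion,
                }
            ),
            "belt_vectors": {
                c: self.belt_table()[c].tolist() for c in self.belt_table().columns
            },
            "warnings": self.warnings,
        }


def analyze(
    trees: Sequence[TreeRecord],
    spec: TransectSpec,
    config: Optional[Config] = None,
    krummholz_present: Optional[bool] = None,
    cover_grid: Optional[CoverGrid] = None,
    shift_scan: bool = False,
    shift_step: float = 1.0,
) -> EcotoneAnalysis:
    """Run the full pattern-quantification pipeline on one point pattern.

    ``krummholz_present`` defaults to "any record flagged krummholz";
    pass an explicit flag to override.  ``cover_grid`` substitutes an
    externally supplied cover raster for crown rasterization.
    """
    config = config or Config()
    if krummholz_present is None:
        krummholz_present = any(
            t.growth_form == GrowthForm.krummholz for t in trees
        )

    gridded = grid_trees(trees, spec)
    stats = subplot_canopy_heights(gridded, spec)
    max_h, max2_h = belt_max_vectors(stats, spec)
    n_vec = belt_counts(stats, spec)

    abr = abruptness_metrics(max_h, max2_h, spec)
    abr_class = classify_abruptness(abr, krummholz_present, config.thresholds)

    if cover_grid is None:
        cover_grid = rasterize_cover(trees, spec, config.supersample)
    sub_cover = subplot_mean_cover(cover_grid, spec)
    disc = fit_cover_logistic(sub_cover, spec.length, config.thresholds)
    disc_class = classify_discreteness(disc, config.thresholds)

    scan = belt_shift_scan(trees, spec, shift_step) if shift_scan else None

    warnings = list(abr.warnings)
    if not disc.interpretable and disc.message:
        warnings.append(f"discreteness: {disc.message}")
    if abr_class.consensus == "conflicting":
        warnings.append(
            "abruptness metrics contradict each other; manual assessment advised"
        )
    if abr_class.boundary_hits:
        warnings.append(
            "metric(s) exactly at a classification cut: "
            + ", ".join(abr_class.boundary_hits)
        )

    return EcotoneAnalysis(
        spec=spec,
        config=config,
        abruptness=abr,
        discreteness=disc,
        abruptness_class=abr_class,
        discreteness_class=disc_class,
        cover_grid=cover_grid,
        subplot_cover=sub_cover,
        krummholz_present=krummholz_present,
        shift_scan=scan,
        warnings=warnings,
        max_h=max_h.values,
        max2_h=max2_h.values,
        belt_n=n_vec.values,
    )
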