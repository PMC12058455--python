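"""Tree-cover rasterization and the logistic discreteness fit.

Cover is the union of (assumed) circular tree crowns projected onto a
grid of square cells — overlap counts once, so cell values lie in
[0, 1].  Subplot mean cover along the elevational axis is then fitted
with the three-parameter logistic

    C(y) = C_max / (1 + exp(s * (y - y_l)))

whose steepness ``s`` (per m) quantifies the discreteness of the forest
edge: with increasing y uphill and s > 0, cover declines from the
forest plateau ``C_max`` through the transition midpoint ``y_l``.
``C_max`` may exceed 1 (it is a fitted plateau, not a proportion), and
``y_l`` may fall outside the transect — both cases are flagged because
they undermine the interpretability of ``s``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .core import (
    ClassificationThresholds,
    FormatError,
    GeometryError,
    TransectSpec,
    TreeRecord,
)


@dataclass
class CoverGrid:
    """Cover fraction per cell; row 0 is the transect bottom."""

    values: np.ndarray  # shape (n_rows, n_cols) = (length/cell, width/cell)
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise FormatError("cover values must lie in [0, 1]")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


def rasterize_cover(
    trees: Sequence[TreeRecord], spec: TransectSpec, supersample: int = 10
) -> CoverGrid:
    """Project the union of circular crowns onto the cover grid.

    Each cell's value is the fraction of its area inside at least one
    crown disk, estimated on a deterministic ``supersample``² subgrid of
    points per cell (no randomness, reproducible bit-exactly).  Crown
    area outside the transect is ignored.
    """
    s = int(supersample)
    if s < 1:
        raise ValueError("supersample must be >= 1")
    cs = spec.cell_size
    nx = round(spec.width / cs)
    ny = round(spec.length / cs)
    if not math.isclose(nx * cs, spec.width) or not math.isclose(ny * cs, spec.length):
        raise GeometryError("cell_size must divide both width and length")
    sub = cs / s
    # subpoint center coordinates along each axis
    xs = (np.arange(nx * s) + 0.5) * sub
    ys = (np.arange(ny * s) + 0.5) * sub
    covered = np.zeros((ny * s, nx * s), dtype=bool)
    for t in trees:
        if t.crown_diameter is None:
            raise ValueError("every tree needs a crown_diameter for cover")
        r = t.crown_diameter / 2.0
        if r <= 0:
            continue
        j0 = max(0, int((t.x - r) / sub))
        j1 = min(nx * s, int((t.x + r) / sub) + 1)
        i0 = max(0, int((t.y - r) / sub))
        i1 = min(ny * s, int((t.y + r) / sub) + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        dx2 = (xs[j0:j1] - t.x) ** 2
        dy2 = (ys[i0:i1] - t.y) ** 2
        covered[i0:i1, j0:j1] |= dy2[:, None] + dx2[None, :] <= r * r
    cover = covered.reshape(ny, s, nx, s).mean(axis=(1, 3))
    return CoverGrid(values=cover, cell_size=cs)


def subplot_mean_cover(grid: CoverGrid, spec: TransectSpec) -> pd.DataFrame:
    """Average cell cover per subplot.

    Returns one row per subplot with columns ``belt_index``,
    ``subplot_index``, ``y_mid`` (the belt midpoint) and ``mean_cover``.
    The cover cell size must divide the subplot size.
    """
    k = spec.subplot_size / grid.cell_size
    if abs(k - round(k)) > 1e-9:
        raise GeometryError("cell_size must divide subplot_size")
    k = round(k)
    kb = round(spec.belt_width / grid.cell_size)
    n_belts, n_sub = spec.n_belts, spec.subplots_per_belt
    if grid.values.shape != (n_belts * kb, n_sub * k):
        raise GeometryError(
            f"cover grid shape {grid.values.shape} does not match the transect"
        )
    # mean over each belt_width x subplot_size block of cells; belts may be
    # taller than subplots are wide, so block rows use the belt height
    block = grid.values.reshape(n_belts, kb, n_sub, k).mean(axis=(1, 3))
    mids = spec.belt_midpoints
    rows = [
        {
            "belt_index": b + 1,
            "subplot_index": sp + 1,
            "y_mid": mids[b],
            "mean_cover": block[b, sp],
        }
        for b in range(n_belts)
        for sp in range(n_sub)
    ]
    return pd.DataFrame(rows)


class FitStatus(str, enum.Enum):
    ok = "ok"
    midpoint_below_margin = "midpoint_below_margin"
    midpoint_above_transect = "midpoint_above_transect"
    low_forest_cover = "low_forest_cover"
    fit_failed = "fit_failed"


@dataclass
class DiscretenessResult:
    """Fitted logistic parameters with validity diagnostics.

    When ``status`` is not ``ok`` the fitted ``s`` is still carried but
    must not be interpreted as a discreteness estimate.
    """

    c_max: float
    y_l: float
    s: float
    rss: float
    converged: bool
    status: FitStatus
    n_points: int
    message: str = ""

    @property
    def interpretable(self) -> bool:
        return self.status == FitStatus.ok

    def transition_width(self) -> Optional[float]:
        """Width of the 80%-to-20% (of C_max) cover transition, 2·ln(4)/s."""
        if self.s <= 0:
            return None
        return 2.0 * math.log(4.0) / self.s


def _logistic(y: np.ndarray, c_max: float, y_l: float, s: float) -> np.ndarray:
    # expit keeps the tails overflow-free
    return c_max * expit(s * (y_l - y))


def _initial_guesses(
    y: np.ndarray, c: np.ndarray, length: float
) -> tuple[float, float, list[float]]:
    """Start values: plateau from the bottom two belts, midpoint from the
    half-plateau crossing of a monotone-smoothed profile, a small s."""
    order = np.argsort(y)
    ys, cs = y[order], c[order]
    uniq = np.unique(ys)
    bottom = uniq[: min(2, len(uniq))]
    c0 = float(np.mean(cs[np.isin(ys, bottom)]))
    c0 = max(c0, 1e-3)
    # monotone (non-increasing uphill) envelope of the per-y mean profile
    prof_y = uniq
    prof = np.array([cs[ys == u].mean() for u in uniq])
    prof = np.maximum.accumulate(prof[::-1])[::-1]
    below = np.nonzero(prof < c0 / 2)[0]
    y_l0 = float(prof_y[below[0]]) if len(below) else length / 2
    s_starts = [0.1, 0.02, 0.05, 0.2, 0.5]
    return c0, y_l0, s_starts


def fit_cover_logistic(
    points: Sequence[tuple[float, float]] | pd.DataFrame | np.ndarray,
    length: float,
    thresholds: Optional[ClassificationThresholds] = None,
) -> DiscretenessResult:
    """Least-squares fit of the logistic cover decline.

    ``points`` are subplot-level (y, cover) pairs — one point per
    subplot, y at the subplot's belt midpoint — or a DataFrame with
    ``y_mid`` and ``mean_cover`` columns.  The fit constrains s >= 0
    (cover must decline uphill); a solution pinned at s = 0 is reported
    as ``fit_failed``.  ``C_max`` is not capped at 1.

    Status rules (checked in this order after convergence): C_max below
    the minimum forest cover -> ``low_forest_cover``; y_l at or below
    the bottom margin -> ``midpoint_below_margin``; y_l above the
    transect -> ``midpoint_above_transect``.
    """
    th = thresholds or ClassificationThresholds()
    if isinstance(points, pd.DataFrame):
        y = points["y_mid"].to_numpy(dtype=float)
        c = points["mean_cover"].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        y, c = arr[:, 0], arr[:, 1]
    if len(np.unique(y)) < 3:
        raise ValueError("need cover at >= 3 distinct y positions")

    c0, y_l0, s_starts = _initial_guesses(y, c, length)

    def residuals(p):
        return _logistic(y, *p) - c

    best = None
    for s0 in s_starts:
        try:
            sol = least_squares(
                residuals,
                x0=[c0, y_l0, s0],
                bounds=([1e-9, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:  # singular Jacobian etc.: try the next start
            continue
        if best is None or (sol.success and sol.cost < best.cost):
            best = sol
    if best is None or not best.success:
        return DiscretenessResult(
            c_max=float("nan"),
            y_l=float("nan"),
            s=float("nan"),
            rss=float("nan"),
            converged=False,
            status=FitStatus.fit_failed,
            n_points=len(y),
            message="optimizer did not converge from any start",
        )
    c_max, y_l, s = (float(v) for v in best.x)
    rss = float(2 * best.cost)
    if s <= 1e-8:
        return DiscretenessResult(
            c_max=c_max,
            y_l=y_l,
            s=s,
            rss=rss,
            converged=True,
            status=FitStatus.fit_failed,
            n_points=len(y),
            message="steepness pinned at 0: no uphill cover decline found",
        )
    if c_max < th.c_max_min:
        status, msg = FitStatus.low_forest_cover, (
            f"fitted forest cover C_max = {c_max:.3g} is below "
            f"{th.c_max_min}; discreteness is not defined at such low cover"
        )
    elif y_l <= th.y_l_margin_m:
        status, msg = FitStatus.midpoint_below_margin, (
            f"transition midpoint y_l = {y_l:.3g} m is at or below the "
            f"{th.y_l_margin_m}-m bottom margin"
        )
    elif y_l > length:
        status, msg = FitStatus.midpoint_above_transect, (
            f"transition midpoint y_l = {y_l:.3g} m lies above the "
            f"{length}-m transect"
        )
    else:
        status, msg = FitStatus.ok, ""
    return DiscretenessResult(
        c_max=c_max,
        y_l=y_l,
        s=s,
        rss=rss,
        converged=True,
        status=status,
        n_points=len(y),
        message=msg,
    )


def write_cover_grid(grid: CoverGrid, path: str | Path) -> None:
    """Write the cover grid as a flat CSV of cell centers."""
    cs = grid.cell_size
    rows, cols = np.meshgrid(
        np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij"
    )
    pd.DataFrame(
        {
            "cell_x": (cols.ravel() + 0.5) * cs,
            "cell_y": (rows.ravel() + 0.5) * cs,
            "cover": grid.values.ravel(),
        }
    ).to_csv(path, index=False)


def read_cover_grid(path: str | Path, spec: TransectSpec) -> CoverGrid:
    """Read a gridded-cover CSV (cell_x, cell_y, cover at cell centers).

    This is the entry point for externally derived cover (e.g. from
    remote sensing), bypassing crown rasterization.  The grid must cover
    the transect completely at ``spec.cell_size`` resolution and all
    cover values must lie in [0, 1].
    """
    df = pd.read_csv(path)
    for col in ("cell_x", "cell_y", "cover"):
        if col not in df.columns:
            raise FormatError(f"cover-grid CSV {path} lacks column {col}")
    cs = spec.cell_size
    nx = round(spec.width / cs)
    ny = round(spec.length / cs)
    if len(df) != nx * ny:
        raise FormatError(
            f"cover grid has {len(df)} cells, expected {nx * ny} "
            f"({nx} x {ny} at {cs}-m cells)"
        )
    cov = df["cover"].to_numpy(dtype=float)
    if np.any(~np.isfinite(cov)) or cov.min() < 0 or cov.max() > 1:
        raise FormatError("cover values must be finite and within [0, 1]")
    j = np.rint(df["cell_x"].to_numpy() / cs - 0.5).astype(int)
    i = np.rint(df["cell_y"].to_numpy() / cs - 0.5).astype(int)
    if (
        j.min() < 0
        or j.max() >= nx
        or i.min() < 0
        or i.max() >= ny
        or len(set(zip(i, j))) != nx * ny
    ):
        raise FormatError("cover grid cells do not tile the transect")
    values = np.empty((ny, nx))
    values[i, j] = cov
    return CoverGrid(values=values, cell_size=cs)
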