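"""Domain types, configuration, and point-pattern / report I/O.

The coordinate convention used throughout: ``y`` is the upslope distance
from the transect bottom (elevation increases with ``y``), ``x`` runs
across the slope.  Elevational belts are indexed 1 (bottom) to
``n_belts`` (top); belts are half-open intervals ``[low, high)`` except
the topmost belt, which is closed, so every in-bounds tree belongs to
exactly one belt.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd


class EcotoneError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EcotoneError):
    """Malformed input table (missing columns, bad values, broken grid)."""


class EmptyInputError(EcotoneError):
    """Input contained no usable records."""


class GeometryError(EcotoneError):
    """Transect geometry does not divide evenly into belts/subplots/cells."""


class NoForestError(EcotoneError):
    """No belt exceeds the forest cutoff; abruptness metrics are undefined."""


class ScenarioError(EcotoneError):
    """Invalid or numerically unworkable synthetic scenario."""


class GrowthForm(str, enum.Enum):
    tree = "tree"
    krummholz = "krummholz"
    unknown = "unknown"


@dataclass
class TreeRecord:
    """One individual: position (m), total height (m), crown diameter (m)."""

    x: float
    y: float
    height: float
    crown_diameter: Optional[float] = None
    growth_form: GrowthForm = GrowthForm.unknown
    age: Optional[float] = None  # accepted but unused by any metric


def _is_int_multiple(total: float, part: float, tol: float = 1e-9) -> bool:
    ratio = total / part
    return abs(ratio - round(ratio)) < tol and round(ratio) > 0


@dataclass(frozen=True)
class TransectSpec:
    """Transect geometry and grid resolutions.

    Parameters
    ----------
    length : float
        Extent along the elevational gradient (m).
    width : float
        Across-slope extent (m).
    belt_width : float
        Width of one elevational belt (m), default 5.
    subplot_size : float
        Edge length of the square subplots within each belt (m), default 5.
    cell_size : float
        Edge of the cover-raster cells (m), default 1.
    seedling_cutoff : float
        Minimum height (m, strict) for an individual to count in
        canopy-height and density statistics, default 0.5.
    forest_cutoff : float
        Canopy-height truncation threshold (m), default 3.
    """

    length: float
    width: float
    belt_width: float = 5.0
    subplot_size: float = 5.0
    cell_size: float = 1.0
    seedling_cutoff: float = 0.5
    forest_cutoff: float = 3.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise GeometryError("transect length and width must be positive")
        if not _is_int_multiple(self.length, self.belt_width):
            raise GeometryError(
                f"length {self.length} is not an integer multiple of "
                f"belt_width {self.belt_width}"
            )
        if not _is_int_multiple(self.width, self.subplot_size):
            raise GeometryError(
                f"width {self.width} is not an integer multiple of "
                f"subplot_size {self.subplot_size}"
            )

    @property
    def n_belts(self) -> int:
        return round(self.length / self.belt_width)

    @property
    def subplots_per_belt(self) -> int:
        return round(self.width / self.subplot_size)

    @property
    def belt_midpoints(self) -> np.ndarray:
        """y coordinate of each belt center, belt 1 first."""
        return (np.arange(1, self.n_belts + 1) - 0.5) * self.belt_width

    def belt_of(self, y: float) -> int:
        """1-based belt index of an in-bounds y (top edge joins top belt)."""
        idx = int(y // self.belt_width) + 1
        return min(idx, self.n_belts)

    def subplot_of(self, x: float) -> int:
        """1-based subplot (column) index of an in-bounds x."""
        idx = int(x // self.subplot_size) + 1
        return min(idx, self.subplots_per_belt)


@dataclass(frozen=True)
class ClassificationThresholds:
    """Threshold conventions for mapping metrics to categorical forms.

    Absolute abruptness cuts are in metres of canopy-height decline per
    belt; normalized cuts are dimensionless; ``s_discrete`` is per metre.
    ``krummholz_reduction_m`` is subtracted from all absolute cuts when a
    krummholz belt is present.
    """

    n_abr_gradual: float = 0.25
    n_abr_abrupt: float = 0.40
    a_abr_gradual_m: float = 2.0
    a_abr_abrupt_m: float = 3.0
    a_abr2_gradual_m: float = 1.5
    krummholz_reduction_m: float = 1.0
    s_discrete: float = 0.2
    c_max_min: float = 0.4
    y_l_margin_m: float = 5.0

    def __post_init__(self) -> None:
        vals = dataclasses.asdict(self)
        if any(v <= 0 for v in vals.values()):
            raise ValueError("all classification thresholds must be positive")
        if not (self.n_abr_gradual < self.n_abr_abrupt):
            raise ValueError("gradual cut must lie below abrupt cut (n_abr)")
        if not (self.a_abr_gradual_m < self.a_abr_abrupt_m):
            raise ValueError("gradual cut must lie below abrupt cut (a_abr)")


@dataclass(frozen=True)
class Config:
    """Run configuration shared across the pipeline.

    ``crown_ratio`` is the crown-diameter-to-height ratio used to fill
    missing crown diameters (default 1/2, i.e. crown diameter is half
    the tree height).  It only affects cover/discreteness outputs; the
    abruptness metrics use heights alone.
    """

    crown_ratio: float = 0.5
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds
    )
    supersample: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.crown_ratio <= 0:
            raise ValueError("crown_ratio must be positive")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")


@dataclass
class PointPatternLoad:
    """Validated records plus a load report."""

    records: list[TreeRecord]
    n_rows: int
    n_dropped_out_of_bounds: int
    n_dropped_bad_height: int
    n_crown_filled: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


_REQUIRED_COLUMNS = ("x", "y", "height")


def read_point_pattern(
    path: str | Path, spec: TransectSpec, config: Config
) -> PointPatternLoad:
    """Read a tree point pattern from CSV and validate it against the transect.

    The CSV must have a header with at least ``x``, ``y`` and ``height``;
    ``crown_diameter``, ``growth_form`` and ``age`` are optional.  Records
    outside the transect rectangle or with non-positive height are dropped
    and counted.  Missing crown diameters are filled as
    ``crown_ratio * height``.

    Raises
    ------
    FormatError
        If a required column is missing.
    EmptyInputError
        If no valid record remains.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise FormatError(f"cannot parse point-pattern CSV {path}: {e}") from e
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"point-pattern CSV {path} lacks column(s) {missing}")

    n_rows = len(df)
    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    h = pd.to_numeric(df["height"], errors="coerce")

    in_bounds = (x >= 0) & (x <= spec.width) & (y >= 0) & (y <= spec.length)
    in_bounds &= x.notna() & y.notna()
    good_height = h.notna() & (h > 0)
    keep = in_bounds & good_height
    n_oob = int((~in_bounds).sum())
    n_bad_h = int((in_bounds & ~good_height).sum())

    crown = None
    if "crown_diameter" in df.columns:
        crown = pd.to_numeric(df["crown_diameter"], errors="coerce")
    form = df["growth_form"] if "growth_form" in df.columns else None
    age = pd.to_numeric(df["age"], errors="coerce") if "age" in df.columns else None

    records: list[TreeRecord] = []
    n_filled = 0
    for i in df.index[keep]:
        cd = None if crown is None else crown[i]
        if cd is None or not np.isfinite(cd) or cd <= 0:
            cd = config.crown_ratio * h[i]
            n_filled += 1
        gf = GrowthForm.unknown
        if form is not None and isinstance(form[i], str):
            try:
                gf = GrowthForm(form[i].strip().lower())
            except ValueError:
                gf = GrowthForm.unknown
        a = None
        if age is not None and np.isfinite(age[i]):
            a = float(age[i])
        records.append(
            TreeRecord(
                x=float(x[i]),
                y=float(y[i]),
                height=float(h[i]),
                crown_diameter=float(cd),
                growth_form=gf,
                age=a,
            )
        )
    if not records:
        raise EmptyInputError(f"no valid tree records in {path}")
    return PointPatternLoad(
        records=records,
        n_rows=n_rows,
        n_dropped_out_of_bounds=n_oob,
        n_dropped_bad_height=n_bad_h,
        n_crown_filled=n_filled,
    )


def write_point_pattern(records: list[TreeRecord], path: str | Path) -> None:
    """Write records back to the standard point-pattern CSV."""
    rows = [
        {
            "x": r.x,
            "y": r.y,
            "height": r.height,
            "crown_diameter": r.crown_diameter,
            "growth_form": r.growth_form.value,
            "age": r.age,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonable(obj):
    """Recursively convert results (dataclasses, arrays, enums) to JSON types."""
    if obj is None or isinstance(obj, (str, bool, int)):
        return obj
    if isinstance(obj, float):
        return obj if math.isfinite(obj) else None
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return _jsonable(obj.item())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return str(obj)


def write_report(report: dict, path: str | Path) -> None:
    """Write the combined JSON report (metrics, classes, thresholds, vectors)."""
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_jsonable(report), fh, indent=2)
            fh.write("\n")
    except OSError as e:
        raise EcotoneError(f"cannot write report to {path}: {e}") from e


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
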