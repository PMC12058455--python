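"""Synthetic treeline-ecotone generator with known ground truth.

Generates idealized hillslope point patterns spanning the two pattern
axes: canopy height either declines linearly uphill (gradual) or drops
in a single step (abrupt), while target tree cover follows the logistic
``C(y) = C_max / (1 + exp(s (y - y_l)))`` — steep (discrete) or shallow
(diffuse).

Trees are placed by an inhomogeneous Poisson process.  Because union
cover of overlapping crowns saturates, the local intensity uses the
Boolean-model (Poisson germ-grain) inversion

    lambda(y) = -ln(1 - C(y)) / (pi * E[r(y)^2])

where ``r(y)`` is the local expected crown radius, so the *expected*
union cover matches the target exactly away from the transect edges.
The generator is deliberately simple: complete spatial randomness (no
clustering or inhibition), no demography — it emulates end-state
patterns, not their dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import yaml

from .core import GrowthForm, ScenarioError, TransectSpec, TreeRecord


@dataclass(frozen=True)
class GradualLinearHeight:
    """Canopy height declining linearly from h_max at y=0 to 0 at y_top."""

    h_max: float
    y_top: float

    def __call__(self, y: np.ndarray) -> np.ndarray:
        return self.h_max * np.clip(1.0 - np.asarray(y) / self.y_top, 0.0, None)


@dataclass(frozen=True)
class AbruptStepHeight:
    """Full forest height below y_step, residual (sub-seedling) height above."""

    h_max: float
    y_step: float
    residual_height: float = 0.3

    def __call__(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y)
        return np.where(y < self.y_step, self.h_max, self.residual_height)


HeightForm = Union[GradualLinearHeight, AbruptStepHeight]


@dataclass(frozen=True)
class CoverProfile:
    """Target logistic cover: c_max, midpoint y_mid (m), steepness (per m)."""

    c_max: float
    y_mid: float
    steepness: float

    def __call__(self, y: np.ndarray) -> np.ndarray:
        z = np.clip(self.steepness * (np.asarray(y) - self.y_mid), -700, 700)
        return self.c_max / (1.0 + np.exp(z))


@dataclass(frozen=True)
class KrummholzBelt:
    """Height cap applied within [y_min, y_max]; capped trees are krummholz."""

    y_min: float
    y_max: float
    cap_height: float


@dataclass
class EcotoneScenario:
    """A fully specified synthetic ecotone.

    ``noise`` is the relative height-noise fraction: realized heights are
    ``H(y) * (1 - noise * U)`` with U ~ Uniform(0, 1).  ``height_floor``
    is the minimum height used when *placing* trees where the height
    profile approaches zero (keeps the Poisson intensity finite); placed
    individuals this small stay below the seedling cutoff.
    """

    spec: TransectSpec = field(default_factory=lambda: TransectSpec(180.0, 60.0))
    height: HeightForm = field(
        default_factory=lambda: GradualLinearHeight(h_max=10.0, y_top=180.0)
    )
    cover: CoverProfile = field(
        default_factory=lambda: CoverProfile(c_max=0.6, y_mid=90.0, steepness=0.1)
    )
    krummholz: Optional[KrummholzBelt] = None
    noise: float = 0.1
    crown_ratio: float = 0.5
    seed: int = 0
    height_floor: float = 0.3
    max_intensity: float = 10.0  # trees per m^2; guard against blow-up

    def __post_init__(self) -> None:
        if not (0 < self.cover.c_max <= 1):
            raise ScenarioError("C_max_true must lie in (0, 1]")
        if self.cover.steepness < 0:
            raise ScenarioError("true steepness s must be >= 0")
        if not (0 <= self.noise < 1):
            raise ScenarioError("noise fraction must lie in [0, 1)")
        if self.crown_ratio <= 0:
            raise ScenarioError("crown_ratio must be positive")
        if self.height_floor <= 0:
            raise ScenarioError("height_floor must be positive")
        if isinstance(self.height, AbruptStepHeight):
            if not (0 <= self.height.residual_height < self.spec.seedling_cutoff):
                raise ScenarioError(
                    "residual height above an abrupt step must stay below the "
                    f"seedling cutoff ({self.spec.seedling_cutoff} m)"
                )


@dataclass
class GroundTruth:
    """True generating parameters returned alongside the pattern."""

    c_max_true: float
    y_l_true: float
    s_true: float
    h_max: float
    form_height: str
    step_height: Optional[float]  # canopy step (m) for abrupt forms
    krummholz_present: bool
    seed: int


def generate_ecotone(
    scenario: EcotoneScenario, seed: Optional[int] = None
) -> tuple[list[TreeRecord], GroundTruth]:
    """Draw one point pattern from the scenario.

    Deterministic given (scenario, seed); ``seed`` overrides
    ``scenario.seed`` when given.  Trees are sampled strip-by-strip
    (1-m strips along y) from the inhomogeneous Poisson process.

    Raises
    ------
    ScenarioError
        If the required intensity exceeds ``scenario.max_intensity``
        anywhere (target cover too high for the local crown size).
    """
    sp = scenario.spec
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    dy = 1.0
    edges = np.arange(0.0, sp.length + dy / 2, dy)
    mids = (edges[:-1] + edges[1:]) / 2

    h_mid = scenario.height(mids)
    c_mid = np.clip(scenario.cover(mids), 0.0, 0.999)
    h_place = np.maximum(h_mid, scenario.height_floor)
    r_mid = 0.5 * scenario.crown_ratio * h_place
    # expected squared radius under the multiplicative height noise
    noise_factor = 1.0 - scenario.noise + scenario.noise**2 / 3.0
    lam = -np.log1p(-c_mid) / (math.pi * r_mid**2 * noise_factor)
    lam[h_mid <= 0] = 0.0
    lam[c_mid <= 0] = 0.0
    if np.any(lam > scenario.max_intensity):
        k = int(np.argmax(lam))
        raise ScenarioError(
            f"required intensity {lam[k]:.2f} trees/m^2 at y = {mids[k]:.0f} m "
            f"exceeds max_intensity = {scenario.max_intensity}; lower the "
            "target cover where trees are small, or raise height_floor"
        )

    records: list[TreeRecord] = []
    for i, lam_i in enumerate(lam):
        n = rng.poisson(lam_i * sp.width * dy)
        if n == 0:
            continue
        xs = rng.uniform(0.0, sp.width, n)
        ys = rng.uniform(edges[i], edges[i + 1], n)
        u = rng.uniform(0.0, 1.0, n)
        h_true = np.maximum(
            np.asarray(scenario.height(ys)), scenario.height_floor
        )
        heights = h_true * (1.0 - scenario.noise * u)
        for x, y, h in zip(xs, ys, heights):
            form = GrowthForm.tree
            if scenario.krummholz is not None and (
                scenario.krummholz.y_min <= y <= scenario.krummholz.y_max
            ):
                if h > scenario.krummholz.cap_height:
                    h = scenario.krummholz.cap_height
                form = GrowthForm.krummholz
            records.append(
                TreeRecord(
                    x=float(x),
                    y=float(y),
                    height=float(h),
                    crown_diameter=float(scenario.crown_ratio * h),
                    growth_form=form,
                )
            )

    if isinstance(scenario.height, AbruptStepHeight):
        form_name, step = "abrupt_step", scenario.height.h_max
    else:
        form_name, step = "gradual_linear", None
    truth = GroundTruth(
        c_max_true=scenario.cover.c_max,
        y_l_true=scenario.cover.y_mid,
        s_true=scenario.cover.steepness,
        h_max=scenario.height.h_max,
        form_height=form_name,
        step_height=step,
        krummholz_present=scenario.krummholz is not None,
        seed=scenario.seed if seed is None else seed,
    )
    return records, truth


# ---------------------------------------------------------------------------
# scenario (de)serialization and presets

def scenario_to_dict(sc: EcotoneScenario) -> dict:
    d = {
        "length": sc.spec.length,
        "width": sc.spec.width,
        "belt_width": sc.spec.belt_width,
        "subplot_size": sc.spec.subplot_size,
        "cell_size": sc.spec.cell_size,
        "c_max": sc.cover.c_max,
        "y_mid": sc.cover.y_mid,
        "steepness": sc.cover.steepness,
        "noise": sc.noise,
        "crown_ratio": sc.crown_ratio,
        "seed": sc.seed,
    }
    if isinstance(sc.height, AbruptStepHeight):
        d.update(
            form_height="abrupt_step",
            h_max=sc.height.h_max,
            y_step=sc.height.y_step,
            residual_height=sc.height.residual_height,
        )
    else:
        d.update(
            form_height="gradual_linear", h_max=sc.height.h_max, y_top=sc.height.y_top
        )
    if sc.krummholz is not None:
        d.update(
            krummholz_y_min=sc.krummholz.y_min,
            krummholz_y_max=sc.krummholz.y_max,
            krummholz_cap_height=sc.krummholz.cap_height,
        )
    return d


def scenario_from_dict(d: dict) -> EcotoneScenario:
    """Build a scenario from the flat key-value form used in YAML files."""
    d = dict(d)
    spec = TransectSpec(
        length=float(d.get("length", 180.0)),
        width=float(d.get("width", 60.0)),
        belt_width=float(d.get("belt_width", 5.0)),
        subplot_size=float(d.get("subplot_size", 5.0)),
        cell_size=float(d.get("cell_size", 1.0)),
    )
    form = d.get("form_height", "gradual_linear")
    if form == "abrupt_step":
        height: HeightForm = AbruptStepHeight(
            h_max=float(d.get("h_max", 8.0)),
            y_step=float(d.get("y_step", spec.length / 2)),
            residual_height=float(d.get("residual_height", 0.3)),
        )
    elif form == "gradual_linear":
        height = GradualLinearHeight(
            h_max=float(d.get("h_max", 10.0)),
            y_top=float(d.get("y_top", spec.length)),
        )
    else:
        raise ScenarioError(f"unknown form_height {form!r}")
    cover = CoverProfile(
        c_max=float(d.get("c_max", 0.6)),
        y_mid=float(d.get("y_mid", spec.length / 2)),
        steepness=float(d.get("steepness", 0.1)),
    )
    kz = None
    if "krummholz_y_min" in d:
        kz = KrummholzBelt(
            y_min=float(d["krummholz_y_min"]),
            y_max=float(d["krummholz_y_max"]),
            cap_height=float(d.get("krummholz_cap_height", 1.5)),
        )
    return EcotoneScenario(
        spec=spec,
        height=height,
        cover=cover,
        krummholz=kz,
        noise=float(d.get("noise", 0.1)),
        crown_ratio=float(d.get("crown_ratio", 0.5)),
        seed=int(d.get("seed", 0)),
    )


def scenario_from_yaml(path) -> EcotoneScenario:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if isinstance(d, dict) and "preset" in d:
        base = scenario_to_dict(preset(d.pop("preset")))
        base.update(d)
        d = base
    if not isinstance(d, dict):
        raise ScenarioError(f"scenario file {path} is not a key-value mapping")
    return scenario_from_dict(d)


_PRESETS = {
    "gradual_diffuse": dict(
        form_height="gradual_linear", h_max=10.0, y_top=180.0,
        c_max=0.6, y_mid=90.0, steepness=0.05,
    ),
    # height reaches shrub stature near the discrete forest edge, so the
    # height decline stays gradual while cover drops steeply
    "gradual_discrete": dict(
        form_height="gradual_linear", h_max=10.0, y_top=100.0,
        c_max=0.6, y_mid=90.0, steepness=0.4,
    ),
    # cover midpoints sit below the height step so the cover transition is
    # carried by tree-stature individuals, not by dense residual vegetation
    "abrupt_diffuse": dict(
        form_height="abrupt_step", h_max=8.0, y_step=100.0, residual_height=0.4,
        c_max=0.6, y_mid=70.0, steepness=0.05,
    ),
    "abrupt_discrete": dict(
        form_height="abrupt_step", h_max=8.0, y_step=100.0,
        c_max=0.6, y_mid=95.0, steepness=0.4,
    ),
}


def preset(name: str) -> EcotoneScenario:
    """One of the four idealized corner forms on the 180 x 60 m transect."""
    try:
        return scenario_from_dict(dict(_PRESETS[name]))
    except KeyError:
        raise ScenarioError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# hand-traceable belt-vector fixtures

@dataclass(frozen=True)
class WorkedVector:
    """A small belt vector with its hand-traced pipeline stages."""

    name: str
    raw: tuple
    forest_cutoff: float
    y_t: int
    truncated: tuple
    smoothed: tuple
    a_abr: float
    n_abr: float


def generate_worked_vectors() -> dict[str, WorkedVector]:
    """Fixtures whose truncation/smoothing/metrics were traced by hand."""
    return {
        "trace1": WorkedVector(
            name="trace1",
            raw=(10, 12, 8, 4, 2, 1, 0),
            forest_cutoff=3.0,
            y_t=4,
            truncated=(4, 4, 4, 4, 2, 1, 0),
            smoothed=(4, 4, 4, 4, 2, 1, 0),
            a_abr=2.0,
            n_abr=2.0 / 12.0,
        ),
        "gap1": WorkedVector(
            name="gap1",
            raw=(10, 12, 8, 4, 0, 2, 0),
            forest_cutoff=3.0,
            y_t=4,
            truncated=(4, 4, 4, 4, 0, 2, 0),
            smoothed=(4, 4, 4, 4, 2, 2, 0),
            a_abr=2.0,
            n_abr=2.0 / 12.0,
        ),
        "flat": WorkedVector(
            name="flat",
            raw=(5, 5, 5),
            forest_cutoff=3.0,
            y_t=3,
            truncated=(5, 5, 5),
            smoothed=(5, 5, 5),
            a_abr=0.0,
            n_abr=0.0,
        ),
    }
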