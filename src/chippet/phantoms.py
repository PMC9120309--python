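"""Emission phantoms and timed positron-decay sampling.

Four source models are provided, mirroring the study conditions of the
scanner concept:

``box``
    The organ-on-chip training phantom: a PMMA box (10 x 26 x 76 mm) whose
    water interior (4 mm shorter per side, i.e. 6 x 22 x 72 mm) emits
    uniformly.  Total activity 1000 Bq.
``line``
    Sensitivity phantom: a 104 mm long, 1 mm thick water cylinder along the
    scanner z axis, 1000 Bq.
``grid21``
    Spatial-resolution phantom: 21 point sources in a 7 (z) x 3 (y) grid
    with 10 mm spacing, centered at the origin in the chip plane, sharing
    1000 Bq.
``ooc_spheres``
    Image-quality phantom: four hot spheres (r = 0.4/0.5/0.6/0.7 mm,
    1000 Bq/mm^3) each nested in a cold r = 2 mm sphere (100 Bq/mm^3),
    the four units spread along z inside the chip water box.

Decays form a homogeneous Poisson process at the phantom's total activity;
positions are drawn uniformly within each emitting region, regions weighted
by their activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Region",
    "SourceModel",
    "DecayEvent",
    "box_source",
    "line_source",
    "grid21_source",
    "ooc_spheres_source",
    "make_source",
    "grid_positions",
    "total_activity",
    "sample_decays",
]

# chip (PMMA) box outer dims, mm: thin axis x, chip plane y-z
PMMA_BOX = np.array([10.0, 26.0, 76.0])
WATER_BOX = PMMA_BOX - 4.0  # 4 mm shorter per side -> 6 x 22 x 72

GRID_SPACING = 10.0  # mm between neighbouring point sources
HOT_RADII = (0.4, 0.5, 0.6, 0.7)  # mm
HOT_CONCENTRATION = 1000.0  # Bq/mm^3
COLD_RADIUS = 2.0  # mm
COLD_CONCENTRATION = 100.0  # Bq/mm^3
SPHERE_UNIT_SPACING = 19.0  # mm along z; not stated by the design, chosen so
#                             four units fit centred in the 72 mm water box


@dataclass(frozen=True)
class Region:
    """One uniformly emitting region.

    kind: "box" (half-size sizes/2 around center), "cylinder" (radius,
    half-length along z), "sphere" (radius) or "point".
    """

    kind: str
    center: np.ndarray
    activity: float  # Bq, total for the region
    params: tuple = ()

    def volume(self) -> float:
        if self.kind == "box":
            return float(np.prod(self.params))
        if self.kind == "cylinder":
            radius, half_len = self.params
            return float(np.pi * radius**2 * 2 * half_len)
        if self.kind == "sphere":
            (radius,) = self.params
            return float(4.0 / 3.0 * np.pi * radius**3)
        return 0.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        if self.kind == "point":
            return np.tile(c, (n, 1))
        if self.kind == "box":
            sizes = np.asarray(self.params, dtype=float)
            return c + (rng.random((n, 3)) - 0.5) * sizes
        if self.kind == "cylinder":
            radius, half_len = self.params
            r = radius * np.sqrt(rng.random(n))
            phi = rng.uniform(0.0, 2 * np.pi, n)
            z = rng.uniform(-half_len, half_len, n)
            return c + np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        if self.kind == "sphere":
            (radius,) = self.params
            v = rng.normal(size=(n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            r = radius * rng.random(n) ** (1.0 / 3.0)
            return c + v * r[:, None]
        raise ValueError(f"unknown region kind {self.kind!r}")


@dataclass(frozen=True)
class SourceModel:
    """A named collection of emitting regions plus attenuation metadata."""

    name: str
    regions: tuple[Region, ...]
    # attenuating structures (material name, Region geometry, mu in 1/mm);
    # consumed by the transport module, no optical role
    attenuators: tuple = ()

    def total_activity(self) -> float:
        return total_activity(self)


def total_activity(source: SourceModel) -> float:
    """Total activity in Bq (sum of region activities)."""
    acts = [r.activity for r in source.regions]
    if any(a < 0 for a in acts):
        raise ValueError("negative region activity")
    return float(sum(acts))


@dataclass(frozen=True)
class DecayEvent:
    event_id: int
    position: np.ndarray  # world mm
    time: float  # s


def _chip_attenuators() -> tuple:
    # PMMA shell + water interior of the chip; mu in 1/mm at 511 keV
    return (
        ("pmma", Region("box", np.zeros(3), 0.0, tuple(PMMA_BOX)), 0.0112),
        ("water", Region("box", np.zeros(3), 0.0, tuple(WATER_BOX)), 0.0096),
    )


def box_source(activity: float = 1000.0) -> SourceModel:
    region = Region("box", np.zeros(3), activity, tuple(WATER_BOX))
    return SourceModel("box", (region,), _chip_attenuators())


def line_source(activity: float = 1000.0, length: float = 104.0,
                radius: float = 0.5) -> SourceModel:
    region = Region("cylinder", np.zeros(3), activity, (radius, length / 2.0))
    atten = (("water", Region("cylinder", np.zeros(3), 0.0, (radius, length / 2.0)),
              0.0096),)
    return SourceModel("line", (region,), atten)


def grid_positions() -> np.ndarray:
    """The 21 point-source positions: 7 along z x 3 along y, 10 mm apart."""
    z = GRID_SPACING * (np.arange(7) - 3.0)
    y = GRID_SPACING * (np.arange(3) - 1.0)
    yy, zz = np.meshgrid(y, z)
    pts = np.column_stack([np.zeros(21), yy.ravel(), zz.ravel()])
    return pts


def grid21_source(activity: float = 1000.0) -> SourceModel:
    pts = grid_positions()
    per_point = activity / len(pts)
    regions = tuple(Region("point", p, per_point) for p in pts)
    return SourceModel("grid21", regions, _chip_attenuators())


def ooc_spheres_source() -> SourceModel:
    """Hot-in-cold sphere phantom.

    Each unit is a hot sphere at 1000 Bq/mm^3 nested in a cold r = 2 mm
    sphere at 100 Bq/mm^3.  The cold activity integrates over the *full*
    cold sphere (the hot core region adds on top of, rather than replaces,
    the cold background), which makes the total come out at 16,537 Bq.
    """
    n = len(HOT_RADII)
    z0 = -SPHERE_UNIT_SPACING * (n - 1) / 2.0
    regions = []
    for i, r_hot in enumerate(HOT_RADII):
        center = np.array([0.0, 0.0, z0 + i * SPHERE_UNIT_SPACING])
        v_hot = 4.0 / 3.0 * np.pi * r_hot**3
        v_cold = 4.0 / 3.0 * np.pi * COLD_RADIUS**3
        regions.append(Region("sphere", center, HOT_CONCENTRATION * v_hot, (r_hot,)))
        regions.append(Region("sphere", center, COLD_CONCENTRATION * v_cold,
                              (COLD_RADIUS,)))
    return SourceModel("ooc_spheres", tuple(regions), _chip_attenuators())


_FACTORIES = {
    "box": box_source,
    "line": line_source,
    "grid21": grid21_source,
    "ooc_spheres": ooc_spheres_source,
}


def make_source(name: str, **kwargs) -> SourceModel:
    """Build a phantom by its run-config name."""
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise ValueError(
            f"unknown phantom {name!r}; choose from {sorted(_FACTORIES)}"
        ) from None
    return factory(**kwargs)


def sample_decays(
    source: SourceModel,
    duration: float | None = None,
    seed: int | np.random.Generator = 0,
    n_events: int | None = None,
) -> list[DecayEvent]:
    """Sample timed decay positions from a phantom.

    With ``duration`` given, the number of decays is Poisson with mean
    activity * duration and times follow a homogeneous Poisson process.
    With ``n_events`` given instead, exactly that many decays are drawn
    (times still exponentially spaced at the phantom rate).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = total_activity(source)
    if n_events is None:
        if duration is None or duration < 0:
            raise ValueError("need duration >= 0 or n_events")
        n = int(rng.poisson(rate * duration)) if rate > 0 else 0
    else:
        n = int(n_events)
    if n == 0:
        return []
    # times: exponential inter-arrivals (strictly increasing almost surely)
    gaps = rng.exponential(1.0 / rate, n) if rate > 0 else np.full(n, np.inf)
    times = np.cumsum(gaps)
    # region assignment weighted by activity
    weights = np.array([r.activity for r in source.regions], dtype=float)
    weights /= weights.sum()
    assignment = rng.choice(len(source.regions), size=n, p=weights)
    positions = np.empty((n, 3))
    for idx, region in enumerate(source.regions):
        mask = assignment == idx
        cnt = int(mask.sum())
        if cnt:
            positions[mask] = region.sample(cnt, rng)
    return [DecayEvent(i, positions[i], float(times[i])) for i in range(n)]
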