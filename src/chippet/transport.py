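"""Simplified annihilation-gamma transport through the scanner.

This module replaces a full Monte Carlo particle transport with an analytic
model sufficient for concept-level studies:

* a positron decay annihilates after an optional isotropic range
  displacement (exponential magnitude, mean 0.6 mm for F-18 in water);
* the two 511 keV gammas leave back-to-back, with an optional acollinearity
  jitter of 0.25 degrees FWHM on the opening angle;
* each gamma survives the phantom materials with Beer-Lambert probability
  and then interacts in the LYSO crystals with probability
  1 - exp(-mu * path), the interaction depth along its chord following a
  (truncated) exponential at mu_LYSO(511 keV);
* the full 511 keV is deposited at a single site (no Compton chains), so
  the first-interaction position and the scintillation position coincide.

Coincidences are decays whose two gammas interact in two *different*
detectors; two interactions in the same detector count as singles only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScannerGeometry
from .phantoms import DecayEvent, SourceModel

__all__ = [
    "PhysicsOptions",
    "GammaInteraction",
    "CoincidenceEvent",
    "annihilate",
    "trace_gamma",
    "simulate_decays",
    "sort_coincidences",
    "sensitivity",
]

C_MM_PER_S = 2.99792458e11  # speed of light


@dataclass(frozen=True)
class PhysicsOptions:
    """Tunable constants of the simplified transport model."""

    mu_lyso_511: float = 0.87  # 1/cm, total linear attenuation of LYSO
    positron_range_enabled: bool = True
    positron_range_mean: float = 0.6  # mm, mean 3D displacement (F-18 in water)
    acollinearity_enabled: bool = True
    acollinearity_fwhm_deg: float = 0.25
    phantom_attenuation_enabled: bool = True
    mu_water_511: float = 0.096  # 1/cm
    mu_pmma_511: float = 0.112  # 1/cm
    coincidence_window_ns: float = 10.0

    def __post_init__(self) -> None:
        for name in ("mu_lyso_511", "positron_range_mean", "acollinearity_fwhm_deg",
                     "mu_water_511", "mu_pmma_511", "coincidence_window_ns"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class GammaInteraction:
    event_id: int
    det_id: int
    position_world: np.ndarray  # mm
    position_local: np.ndarray  # detector-local mm
    time: float  # s
    energy: float = 0.511  # MeV, single-site full deposit


@dataclass(frozen=True)
class CoincidenceEvent:
    first: GammaInteraction
    second: GammaInteraction
    true_coincidence: bool = True


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - u**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), u])


def _perturb_directions(d: np.ndarray, angles: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Rotate each unit vector by its angle about a random transverse axis."""
    n = len(d)
    a = rng.normal(size=(n, 3))
    a -= np.sum(a * d, axis=1, keepdims=True) * d
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    ca, sa = np.cos(angles)[:, None], np.sin(angles)[:, None]
    # Rodrigues with axis orthogonal to d: the (1-cos) term vanishes
    return ca * d + sa * np.cross(a, d, axis=1)


def annihilate_batch(
    positions: np.ndarray, options: PhysicsOptions, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized annihilation: (points, directions1, directions2)."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(pos)
    points = pos.copy()
    if options.positron_range_enabled and options.positron_range_mean > 0:
        mag = rng.exponential(options.positron_range_mean, n)
        points = points + _isotropic_directions(n, rng) * mag[:, None]
    d1 = _isotropic_directions(n, rng)
    d2 = -d1
    if options.acollinearity_enabled and options.acollinearity_fwhm_deg > 0:
        sigma = np.deg2rad(options.acollinearity_fwhm_deg) / 2.355
        angles = rng.normal(0.0, sigma, n)
        d2 = _perturb_directions(d2, angles, rng)
    return points, d1, d2


def annihilate(
    decay: DecayEvent, options: PhysicsOptions, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Annihilation point and the two gamma unit directions for one decay."""
    pts, d1, d2 = annihilate_batch(decay.position[None, :], options, rng)
    return pts[0], d1[0], d2[0]


# ---------------------------------------------------------------------------
# phantom attenuation


def _exit_distance_box(origin: np.ndarray, direction: np.ndarray,
                       half: np.ndarray) -> np.ndarray:
    """Distance from interior points to the exit of a centred AABB (0 outside)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-half - origin) / direction
        t2 = (half - origin) / direction
    t_hi = np.where(np.isnan(t1), np.inf, np.maximum(t1, t2))
    t_exit = t_hi.min(axis=1)
    inside = np.all(np.abs(origin) <= half + 1e-12, axis=1)
    return np.where(inside, np.maximum(t_exit, 0.0), 0.0)


def _exit_distance_cylinder(origin: np.ndarray, direction: np.ndarray,
                            radius: float, half_len: float) -> np.ndarray:
    """Exit distance from interior points of a z-aligned centred cylinder."""
    ox, oy = origin[:, 0], origin[:, 1]
    dx, dy = direction[:, 0], direction[:, 1]
    a = dx**2 + dy**2
    b = ox * dx + oy * dy
    c = ox**2 + oy**2 - radius**2
    disc = np.maximum(b**2 - a * c, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_rad = np.where(a > 0, (-b + np.sqrt(disc)) / a, np.inf)
        t_ax = np.where(
            direction[:, 2] != 0,
            (np.sign(direction[:, 2]) * half_len - origin[:, 2]) / direction[:, 2],
            np.inf,
        )
    inside = (c <= 1e-9) & (np.abs(origin[:, 2]) <= half_len + 1e-12)
    return np.where(inside, np.maximum(np.minimum(t_rad, t_ax), 0.0), 0.0)


def _phantom_path_lengths(
    source: SourceModel, origins: np.ndarray, directions: np.ndarray
) -> dict[str, np.ndarray]:
    """Material path lengths (mm) from each origin to the phantom exit.

    Attenuating structures are convex and nested, so the path through the
    outer material is (outer exit - inner exit).
    """
    exits: list[tuple[str, np.ndarray]] = []
    for material, region, _mu in source.attenuators:
        o = origins - region.center
        if region.kind == "box":
            half = np.asarray(region.params) / 2.0
            exits.append((material, _exit_distance_box(o, directions, half)))
        elif region.kind == "cylinder":
            radius, half_len = region.params
            exits.append((material,
                          _exit_distance_cylinder(o, directions, radius, half_len)))
    if not exits:
        return {}
    # nested ordering: sort by exit distance descending = outermost first
    paths: dict[str, np.ndarray] = {}
    names = [m for m, _ in exits]
    dists = np.column_stack([d for _, d in exits])
    order = np.argsort(-dists.mean(axis=0))
    prev = np.zeros(len(origins))
    for idx in order[::-1]:  # innermost first
        seg = np.maximum(dists[:, idx] - prev, 0.0)
        paths[names[idx]] = paths.get(names[idx], 0.0) + seg
        prev = np.maximum(prev, dists[:, idx])
    return paths


def _phantom_survival(
    source: SourceModel, origins: np.ndarray, directions: np.ndarray,
    options: PhysicsOptions,
) -> np.ndarray:
    if not options.phantom_attenuation_enabled or not source.attenuators:
        return np.ones(len(origins))
    mu = {"water": options.mu_water_511 / 10.0, "pmma": options.mu_pmma_511 / 10.0}
    log_s = np.zeros(len(origins))
    for material, path in _phantom_path_lengths(source, origins, directions).items():
        log_s -= mu.get(material, 0.0) * path
    return np.exp(log_s)


# ---------------------------------------------------------------------------
# crystal tracing


def _crystal_segments(
    geometry: ScannerGeometry, origins: np.ndarray, directions: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ray/crystal chords for every (gamma, crystal) pair.

    Returns (t_in, t_out, det_id) arrays of shape (n, 8); chords with no
    intersection have t_in = t_out.
    """
    n = len(origins)
    records = geometry.crystal_bounds_world()
    t_in = np.zeros((n, len(records)))
    t_out = np.zeros((n, len(records)))
    det_ids = np.zeros(len(records), dtype=int)
    for j, (det_id, tf, bounds) in enumerate(records):
        det_ids[j] = det_id
        o = tf.world_to_local(origins)
        d = tf.rotate_world_to_local(directions)
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = (bounds[0] - o) / d
            tb = (bounds[1] - o) / d
        lo = np.where(np.isnan(ta), -np.inf, np.minimum(ta, tb))
        hi = np.where(np.isnan(ta), np.inf, np.maximum(ta, tb))
        # axes with zero direction component: inside slab -> keep, else miss
        zero = d == 0.0
        inside_slab = (o >= bounds[0]) & (o <= bounds[1])
        lo = np.where(zero, np.where(inside_slab, -np.inf, np.inf), lo)
        hi = np.where(zero, np.where(inside_slab, np.inf, -np.inf), hi)
        tin = np.maximum(lo.max(axis=1), 1e-9)
        tout = hi.min(axis=1)
        miss = tout <= tin
        t_in[:, j] = np.where(miss, 0.0, tin)
        t_out[:, j] = np.where(miss, 0.0, tout)
    return t_in, t_out, det_ids


def trace_gamma_batch(
    origins: np.ndarray,
    directions: np.ndarray,
    geometry: ScannerGeometry,
    options: PhysicsOptions,
    rng: np.random.Generator,
    source: SourceModel | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Trace many gammas; returns (hit_mask, det_id, world_point, path_len).

    The interaction site is sampled by drawing an exponential free path in
    LYSO (rate mu) and walking it through the ordered crystal chords of the
    ray; rays whose total crystal path is shorter escape.
    """
    origins = np.atleast_2d(origins)
    directions = np.atleast_2d(directions)
    n = len(origins)
    mu = options.mu_lyso_511 / 10.0  # 1/mm
    t_in, t_out, det_ids = _crystal_segments(geometry, origins, directions)
    chords = t_out - t_in
    order = np.argsort(np.where(chords > 0, t_in, np.inf), axis=1)
    rows = np.arange(n)[:, None]
    t_in_o = t_in[rows, order]
    chords_o = chords[rows, order]
    det_o = det_ids[order]
    cum = np.cumsum(chords_o, axis=1)
    cum_before = cum - chords_o

    free_path = rng.exponential(1.0 / mu, n) if mu > 0 else np.full(n, np.inf)
    if source is not None:
        survival = _phantom_survival(source, origins, directions, options)
        absorbed = rng.random(n) >= survival
        free_path[absorbed] = np.inf

    hit_seg = (free_path[:, None] > cum_before) & (free_path[:, None] <= cum)
    hit = hit_seg.any(axis=1)
    seg_idx = np.argmax(hit_seg, axis=1)
    t_hit = (
        t_in_o[rows[:, 0], seg_idx]
        + (free_path - cum_before[rows[:, 0], seg_idx])
    )
    points = origins + directions * t_hit[:, None]
    det = det_o[rows[:, 0], seg_idx]
    return hit, det, points, t_hit


def trace_gamma(
    point: np.ndarray,
    direction: np.ndarray,
    geometry: ScannerGeometry,
    options: PhysicsOptions,
    rng: np.random.Generator,
    source: SourceModel | None = None,
    event_id: int = 0,
    time: float = 0.0,
) -> GammaInteraction | None:
    """Trace one gamma; None if it escapes or is absorbed in the phantom."""
    hit, det, pts, path = trace_gamma_batch(
        point[None, :], np.asarray(direction, dtype=float)[None, :],
        geometry, options, rng, source,
    )
    if not hit[0]:
        return None
    det_id = int(det[0])
    local = geometry.world_to_detector(pts[0], det_id)
    return GammaInteraction(
        event_id=event_id,
        det_id=det_id,
        position_world=pts[0],
        position_local=local,
        time=time + float(path[0]) / C_MM_PER_S,
    )


def simulate_decays(
    decays: list[DecayEvent],
    geometry: ScannerGeometry,
    options: PhysicsOptions,
    rng: np.random.Generator,
    source: SourceModel | None = None,
) -> list[GammaInteraction]:
    """Annihilate and trace every decay; returns time-ordered interactions."""
    if not decays:
        return []
    positions = np.array([d.position for d in decays])
    times = np.array([d.time for d in decays])
    ids = np.array([d.event_id for d in decays])
    points, d1, d2 = annihilate_batch(positions, options, rng)
    interactions: list[GammaInteraction] = []
    for dirs in (d1, d2):
        hit, det, pts, path = trace_gamma_batch(
            points, dirs, geometry, options, rng, source
        )
        idx = np.nonzero(hit)[0]
        if len(idx) == 0:
            continue
        for i in idx:
            det_id = int(det[i])
            interactions.append(
                GammaInteraction(
                    event_id=int(ids[i]),
                    det_id=det_id,
                    position_world=pts[i],
                    position_local=geometry.world_to_detector(pts[i], det_id),
                    time=float(times[i]) + float(path[i]) / C_MM_PER_S,
                )
            )
    interactions.sort(key=lambda g: g.time)
    return interactions


def sort_coincidences(
    interactions: list[GammaInteraction], window_ns: float = 10.0
) -> tuple[list[CoincidenceEvent], int, int]:
    """Split time-ordered interactions into (trues, randoms count, singles).

    A true coincidence is the two gammas of one decay interacting in two
    different detectors.  A random pairs interactions of different decays
    within the timing window.  Decays whose two interactions share a
    detector contribute singles only.
    """
    window_s = window_ns * 1e-9
    by_event: dict[int, list[GammaInteraction]] = {}
    for g in interactions:
        by_event.setdefault(g.event_id, []).append(g)
    trues: list[CoincidenceEvent] = []
    singles = 0
    paired_ids = set()
    for eid, group in by_event.items():
        if len(group) == 2 and group[0].det_id != group[1].det_id:
            trues.append(CoincidenceEvent(group[0], group[1], True))
            paired_ids.add(eid)
        else:
            singles += len(group)
    randoms = 0
    if window_s > 0:
        times = np.array([g.time for g in interactions])
        events = np.array([g.event_id for g in interactions])
        dets = np.array([g.det_id for g in interactions])
        j = 0
        for i in range(len(times)):
            j = max(j, i + 1)
            while j < len(times) and times[j] - times[i] <= window_s:
                j += 1
            for k in range(i + 1, j):
                if events[k] != events[i] and dets[k] != dets[i]:
                    randoms += 1
    trues.sort(key=lambda c: c.first.time)
    return trues, randoms, singles


def sensitivity(
    source: SourceModel,
    geometry: ScannerGeometry,
    options: PhysicsOptions | None = None,
    n_events: int | None = 10_000,
    duration: float | None = None,
    seed: int | np.random.Generator = 0,
) -> float:
    """Coincidence sensitivity: true coincidences / total decays."""
    from .phantoms import sample_decays

    options = options or PhysicsOptions()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    decays = sample_decays(source, duration=duration, seed=rng, n_events=n_events)
    if not decays:
        raise ValueError("sensitivity undefined for zero decays")
    interactions = simulate_decays(decays, geometry, options, rng, source)
    trues, _, _ = sort_coincidences(interactions, options.coincidence_window_ns)
    return len(trues) / len(decays)
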