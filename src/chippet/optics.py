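"""Analytic scintillation-light transport and SiPM response.

A 511 keV deposit in the LYSO produces a Gaussian-fluctuating photon burst
(yield 40,000 /MeV, resolution scale 4.8).  Photons reach each SiPM channel
in direct line of sight: the arrival probability of a channel is the solid
angle of its pitch-square patch seen from the scintillation point, divided
by 4*pi, damped by bulk absorption exp(-r / lambda_abs).  No reflections
are modelled (polished, un-wrapped crystal; a ``reflection_boost`` scalar
can approximate recovered light).  Channel outputs then follow a counting
SiPM model: photon detection efficiency x fill factor thinning, dark
counts over the integration gate, one generation of optical crosstalk, an
afterpulse gain, and pixel saturation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DetectorSpec, ScannerGeometry, SurfaceGrid, surface_grids
from .transport import GammaInteraction

__all__ = [
    "ScintillatorSpec",
    "SiPMSpec",
    "LightPattern",
    "LightPatternSet",
    "rect_solid_angle",
    "photon_yield",
    "channel_weights",
    "channel_weight",
    "distribute_photons",
    "sipm_response",
    "SurfaceOptics",
    "make_pattern_set",
    "pattern_sets_from_padded",
    "PADDED_SIZES",
]

#: Padded square pattern size per SiPM size (set by the 104.4 mm back-surface
#: axis: 32, 24 or 16 channels).
PADDED_SIZES = {3.0: 32, 4.0: 24, 6.0: 16}

PIXELS_PER_CHANNEL = {3.0: 3531, 4.0: 6331, 6.0: 14331}


@dataclass(frozen=True)
class ScintillatorSpec:
    """LYSO scintillation constants."""

    light_yield: float = 40_000.0  # photons / MeV
    resolution_scale: float = 4.8  # broadens Poisson-like yield fluctuations
    fast_time_constant_ns: float = 36.0
    absorption_length: float = 400.0  # mm, bulk optical absorption

    def __post_init__(self) -> None:
        if self.light_yield <= 0 or self.resolution_scale < 1:
            raise ValueError("need light_yield > 0 and resolution_scale >= 1")


@dataclass(frozen=True)
class SiPMSpec:
    """One Hamamatsu-style SiPM channel model."""

    size: float = 3.0  # mm, photosensitive area side
    pixels_per_channel: int = 3531
    pde: float = 0.50
    fill_factor: float = 0.74
    dark_count_rate: float = 110e3  # Hz / mm^2
    crosstalk_prob: float = 0.07
    afterpulse_prob: float = 0.06
    rise_time_ns: float = 2.0
    fall_time_ns: float = 190.0
    recovery_time_ns: float = 50.0
    integration_gate_ns: float = 300.0

    def __post_init__(self) -> None:
        for p in (self.pde, self.fill_factor, self.crosstalk_prob,
                  self.afterpulse_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("SiPM probabilities must lie in [0, 1]")

    @classmethod
    def for_size(cls, size: float, **overrides) -> "SiPMSpec":
        overrides.setdefault("pixels_per_channel",
                             PIXELS_PER_CHANNEL[float(size)])
        return cls(size=float(size), **overrides)

    def dark_mean(self, pitch: float) -> float:
        """Expected dark counts per channel over the integration gate."""
        area = pitch**2  # mm^2 per channel footprint
        return self.dark_count_rate * area * self.integration_gate_ns * 1e-9


def photon_yield(energy_mev: float, spec: ScintillatorSpec,
                 rng: np.random.Generator) -> int:
    """Scintillation photon count for one deposit.

    Normal(Y*E, resolution_scale * sqrt(Y*E)), truncated at zero, rounded.
    """
    if energy_mev <= 0:
        raise ValueError("energy must be positive")
    mean = spec.light_yield * energy_mev
    n = rng.normal(mean, spec.resolution_scale * np.sqrt(mean))
    return int(round(max(n, 0.0)))


def rect_solid_angle(du1, du2, dv1, dv2, d):
    """Solid angle of an axis-aligned rectangle seen from a point.

    The rectangle spans [du1, du2] x [dv1, dv2] in the plane at normal
    distance ``d`` from the point, coordinates relative to the foot of the
    perpendicular.  Signed-corner decomposition of the standard
    pyramid-solid-angle formula; valid for any point position.
    """
    def corner(a, b):
        return np.arctan2(a * b, d * np.sqrt(a * a + b * b + d * d))

    return corner(du2, dv2) - corner(du1, dv2) - corner(du2, dv1) + corner(du1, dv1)


# surface -> (normal axis, plane coordinate picker, (u axis, v axis))
_SURFACE_FRAMES = {
    "back": (1, "max", (0, 2)),
    "left": (0, "min", (1, 2)),
    "right": (0, "max", (1, 2)),
    "top": (2, "max", (0, 1)),
    "bottom": (2, "min", (0, 1)),
}


class SurfaceOptics:
    """Precomputed channel geometry for the five grids of one detector.

    Channel arrival weights combine three factors: the direct line-of-sight
    solid angle of the channel's pitch-square patch, bulk absorption
    exp(-r / lambda_abs), and — unless ``escape_cone_enabled`` is off — a
    total-internal-reflection cutoff at the crystal/coupling boundary:
    light striking a surface beyond the critical angle
    asin(n_coupling / n_crystal) is trapped and (with reflections not
    modelled) lost.  Without the cutoff the grazing-incidence tails of the
    solid angle spread far along each surface, which no real polished
    crystal exhibits.
    """

    def __init__(self, detector: DetectorSpec, sipm_size: float,
                 scintillator: ScintillatorSpec | None = None,
                 reflection_boost: float = 1.0,
                 escape_cone_enabled: bool = True,
                 n_crystal: float = 1.82, n_coupling: float = 1.5):
        self.detector = detector
        self.sipm_size = float(sipm_size)
        self.scintillator = scintillator or ScintillatorSpec()
        self.reflection_boost = reflection_boost
        self.escape_cone_enabled = escape_cone_enabled
        self.cos_critical = (np.sqrt(max(1.0 - (n_coupling / n_crystal) ** 2,
                                         0.0))
                             if escape_cone_enabled else 0.0)
        self.grids = surface_grids(detector, sipm_size)
        self._planes = {}
        dims = (detector.size_x, detector.size_y, detector.size_z)
        for name, (axis, side, (ua, va)) in _SURFACE_FRAMES.items():
            grid = self.grids[name]
            uu, vv = np.meshgrid(grid.centers_u, grid.centers_v, indexing="ij")
            plane = dims[axis] if side == "max" else 0.0
            self._planes[name] = (axis, plane, ua, va, uu.ravel(), vv.ravel(),
                                  grid.pitch / 2.0)
        self.n_channels = {n: g.n_channels for n, g in self.grids.items()}
        self.total_channels = sum(self.n_channels.values())

    def weights(self, point: np.ndarray) -> dict[str, np.ndarray]:
        """Per-channel arrival probabilities for a scintillation point."""
        p = np.asarray(point, dtype=float)
        lam = self.scintillator.absorption_length
        out = {}
        for name, (axis, plane, ua, va, cu, cv, half) in self._planes.items():
            d = abs(p[axis] - plane)
            du, dv = cu - p[ua], cv - p[va]
            omega = rect_solid_angle(du - half, du + half, dv - half, dv + half, d)
            r = np.sqrt(d * d + du * du + dv * dv)
            w = omega / (4.0 * np.pi) * np.exp(-r / lam) * self.reflection_boost
            if self.escape_cone_enabled:
                # a channel is reachable if the nearest point of its patch
                # lies inside the critical cone's footprint on the surface;
                # evaluating at the centre instead would let deep events
                # fall between channels entirely
                near_u = np.maximum(np.abs(du) - half, 0.0)
                near_v = np.maximum(np.abs(dv) - half, 0.0)
                near = np.hypot(near_u, near_v)
                hyp = np.hypot(near, d)
                cos_near = np.where(hyp > 0, d / np.maximum(hyp, 1e-300), 1.0)
                w = np.where(cos_near >= self.cos_critical, w, 0.0)
            out[name] = w
        return out


def channel_weights(point: np.ndarray, optics: SurfaceOptics) -> dict[str, np.ndarray]:
    return optics.weights(point)


def channel_weight(point: np.ndarray, optics: SurfaceOptics, surface: str,
                   channel: tuple[int, int]) -> float:
    """Weight of a single (surface, channel) as seen from ``point``."""
    grid = optics.grids[surface]
    w = optics.weights(point)[surface].reshape(grid.n_u, grid.n_v)
    return float(w[channel])


def distribute_photons(
    n_photons: int,
    weights: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], int]:
    """Multinomial photon split over all channels plus an escape sink.

    Returns (per-surface arrival counts, escaped count); arrivals conserve
    the photon budget exactly.
    """
    if n_photons < 0:
        raise ValueError("photon count must be non-negative")
    names = list(weights)
    flat = np.concatenate([weights[n] for n in names])
    escape = max(1.0 - flat.sum(), 0.0)
    probs = np.append(flat, escape)
    probs = probs / probs.sum()
    counts = rng.multinomial(int(n_photons), probs)
    out = {}
    k = 0
    for n in names:
        m = len(weights[n])
        out[n] = counts[k:k + m]
        k += m
    return out, int(counts[-1])


def sipm_response(
    arrivals: np.ndarray,
    spec: SiPMSpec,
    rng: np.random.Generator,
    pitch: float | None = None,
) -> np.ndarray:
    """Channel output values from photon arrival counts.

    detected ~ Binomial(arrivals, PDE * fill factor); one crosstalk
    generation; afterpulsing as a (1 + p_ap) gain; dark counts
    ~ Poisson(DCR * area * gate) added; pixel saturation
    N_pix * (1 - exp(-fired / N_pix)) applied last.
    """
    arrivals = np.asarray(arrivals)
    if np.any(arrivals < 0):
        raise ValueError("arrivals must be non-negative")
    pitch = pitch if pitch is not None else 1.0875 * spec.size
    q = spec.pde * spec.fill_factor
    detected = rng.binomial(arrivals, q)
    detected = detected + rng.binomial(detected, spec.crosstalk_prob)
    amplified = detected * (1.0 + spec.afterpulse_prob)
    dark = rng.poisson(spec.dark_mean(pitch), size=arrivals.shape)
    fired = amplified + dark
    npix = spec.pixels_per_channel
    return npix * (1.0 - np.exp(-fired / npix))


@dataclass
class LightPattern:
    """One surface's channel image, raw and zero-padded to a square."""

    surface_name: str
    raw: np.ndarray  # (n_u, n_v)
    padded: np.ndarray  # (S, S), zeros outside the valid mask
    mask: np.ndarray  # (S, S) bool

    @property
    def total(self) -> float:
        return float(self.raw.sum())


def _pad_square(raw: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    n_u, n_v = raw.shape
    padded = np.zeros((size, size), dtype=raw.dtype)
    mask = np.zeros((size, size), dtype=bool)
    off_u = (size - n_u) // 2
    off_v = (size - n_v) // 2
    padded[off_u:off_u + n_u, off_v:off_v + n_v] = raw
    mask[off_u:off_u + n_u, off_v:off_v + n_v] = True
    return padded, mask


@dataclass
class LightPatternSet:
    """The five per-surface patterns of one detector for one event."""

    event_id: int
    det_id: int
    patterns: dict[str, LightPattern]
    truth_local: np.ndarray  # ground-truth first-interaction position, mm

    def stacked(self, surfaces: tuple[str, ...] | None = None,
                normalize: bool = True) -> np.ndarray:
        """(C, S, S) channel stack for estimator input."""
        from .geometry import SURFACE_NAMES

        surfaces = surfaces or SURFACE_NAMES
        arr = np.stack([self.patterns[s].padded for s in surfaces]).astype(np.float32)
        if normalize:
            peak = arr.max()
            if peak > 0:
                arr = arr / peak
        return arr


def pattern_sets_from_padded(
    patterns: np.ndarray,
    positions: np.ndarray,
    optics: "SurfaceOptics",
) -> list["LightPatternSet"]:
    """Rebuild LightPatternSets from a dataset's (N, 5, S, S) padded stack."""
    from .geometry import SURFACE_NAMES

    out = []
    size = patterns.shape[-1]
    for k in range(len(patterns)):
        pats = {}
        for c, name in enumerate(SURFACE_NAMES):
            grid = optics.grids[name]
            off_u = (size - grid.n_u) // 2
            off_v = (size - grid.n_v) // 2
            padded = np.asarray(patterns[k, c], dtype=np.float64)
            raw = padded[off_u:off_u + grid.n_u, off_v:off_v + grid.n_v]
            _, mask = _pad_square(raw, size)
            pats[name] = LightPattern(name, raw, padded, mask)
        out.append(LightPatternSet(k, 0, pats,
                                   np.asarray(positions[k], dtype=float)))
    return out


def make_pattern_set(
    interaction: GammaInteraction,
    optics: SurfaceOptics,
    sipm: SiPMSpec,
    scintillator: ScintillatorSpec,
    rng: np.random.Generator,
) -> LightPatternSet:
    """Simulate the five light patterns for one gamma interaction."""
    n_photons = photon_yield(interaction.energy, scintillator, rng)
    weights = optics.weights(interaction.position_local)
    arrivals, _ = distribute_photons(n_photons, weights, rng)
    size = PADDED_SIZES[optics.sipm_size]
    patterns = {}
    for name, grid in optics.grids.items():
        outputs = sipm_response(arrivals[name], sipm, rng, pitch=grid.pitch)
        raw = np.asarray(outputs, dtype=np.float64).reshape(grid.n_u, grid.n_v)
        padded, mask = _pad_square(raw, size)
        patterns[name] = LightPattern(name, raw, padded, mask)
    return LightPatternSet(
        event_id=interaction.event_id,
        det_id=interaction.det_id,
        patterns=patterns,
        truth_local=np.asarray(interaction.position_local, dtype=float),
    )
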