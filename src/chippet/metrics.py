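"""Image-quality metrics: line-profile FWHM, sphere SNR, peak counting.

All measurements operate on reconstructed plane images and take ground
truth source coordinates as input.  Profiles are smoothed with a Gaussian
of sigma 0.5 pixels before any peak measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.feature import peak_local_max

from .reconstruction import ReconImage

__all__ = [
    "LineProfile",
    "QualityReport",
    "line_profile",
    "fwhm_at",
    "snr_at",
    "count_peaks",
]

PROFILE_SIGMA_PX = 0.5
SEARCH_WINDOW_MM = 5.0
SNR_CAP_DB = 60.0


@dataclass
class LineProfile:
    """One axis-aligned intensity profile through a target point."""

    axis: str  # "a" (horizontal, along columns) or "b" (vertical)
    positions: np.ndarray  # mm along the profile, plane coordinates
    intensity: np.ndarray  # smoothed samples
    raw: np.ndarray


def line_profile(recon: ReconImage, point: tuple[float, float],
                 axis: str) -> LineProfile:
    """Extract and smooth the row/column profile through a plane point."""
    i, j = recon.to_pixel(*point)
    n = recon.image.shape[0]
    i = int(np.clip(i, 0, n - 1))
    j = int(np.clip(j, 0, n - 1))
    c = n // 2
    if axis == "a":
        raw = recon.image[i, :]
        positions = (np.arange(n) - c) * recon.pixel_size
    elif axis == "b":
        raw = recon.image[:, j]
        positions = (c - np.arange(n)) * recon.pixel_size
    else:
        raise ValueError("axis must be 'a' or 'b'")
    smoothed = gaussian_filter1d(raw.astype(float), PROFILE_SIGMA_PX)
    return LineProfile(axis, positions, smoothed, raw.astype(float))


def _profile_fwhm(profile: LineProfile, target_mm: float,
                  window_mm: float = SEARCH_WINDOW_MM) -> float | None:
    """FWHM (mm) of the peak nearest the target; None if undefined."""
    pos, y = profile.positions, profile.intensity
    order = np.argsort(pos)
    pos, y = pos[order], y[order]
    sel = np.abs(pos - target_mm) <= window_mm
    if not sel.any() or np.all(y[sel] <= 0):
        return None
    idx_window = np.nonzero(sel)[0]
    peak = idx_window[np.argmax(y[idx_window])]
    half = y[peak] / 2.0
    if y[peak] <= 0:
        return None
    # walk outwards to the half-max crossings, linear interpolation
    left = None
    for k in range(peak, 0, -1):
        if y[k - 1] <= half:
            frac = (y[k] - half) / (y[k] - y[k - 1])
            left = pos[k] - frac * (pos[k] - pos[k - 1])
            break
    right = None
    for k in range(peak, len(y) - 1):
        if y[k + 1] <= half:
            frac = (y[k] - half) / (y[k] - y[k + 1])
            right = pos[k] + frac * (pos[k + 1] - pos[k])
            break
    if left is None or right is None:
        return None
    return float(right - left)


def fwhm_at(recon: ReconImage, point: tuple[float, float],
            axes: tuple[str, ...] = ("a", "b")) -> tuple[float | None, dict]:
    """Mean FWHM (mm) over axis profiles through a point.

    Returns (mean FWHM or None if no axis yields a peak, per-axis dict).
    """
    per_axis: dict[str, float | None] = {}
    for axis in axes:
        prof = line_profile(recon, point, axis)
        target = point[0] if axis == "a" else point[1]
        per_axis[axis] = _profile_fwhm(prof, target)
    values = [v for v in per_axis.values() if v is not None]
    return (float(np.mean(values)) if values else None), per_axis


def snr_at(
    recon: ReconImage,
    hot_center: tuple[float, float],
    cold_offsets_mm: tuple[float, float] = (3.0, 12.0),
    hot_window_mm: float = 2.0,
    axes: tuple[str, ...] = ("a", "b"),
) -> tuple[float, dict]:
    """Signal-to-noise of a hot sphere, in dB, averaged over axis profiles.

    Per profile: SNR = 10 log10(peak amplitude within ``hot_window_mm`` of
    the center / RMS of the cold-background samples at distances within
    ``cold_offsets_mm`` of the center), clamped below at 0 dB and above at
    60 dB (zero cold RMS).
    """
    per_axis: dict[str, float] = {}
    lo, hi = cold_offsets_mm
    for axis in axes:
        prof = line_profile(recon, hot_center, axis)
        target = hot_center[0] if axis == "a" else hot_center[1]
        dist = np.abs(prof.positions - target)
        hot_sel = dist <= hot_window_mm
        cold_sel = (dist > lo) & (dist <= hi)
        if not cold_sel.any():
            raise ValueError("empty cold region on profile")
        peak = float(prof.intensity[hot_sel].max()) if hot_sel.any() else 0.0
        cold_rms = float(np.sqrt(np.mean(prof.intensity[cold_sel] ** 2)))
        if cold_rms == 0.0:
            snr = SNR_CAP_DB if peak > 0 else 0.0
        elif peak <= 0:
            snr = 0.0
        else:
            snr = 10.0 * np.log10(peak / cold_rms)
        per_axis[axis] = float(np.clip(snr, 0.0, SNR_CAP_DB))
    return float(np.mean(list(per_axis.values()))), per_axis


def count_peaks(
    recon: ReconImage,
    min_separation_mm: float = 5.0,
    threshold_frac: float = 0.5,
    smooth_sigma_px: float = PROFILE_SIGMA_PX,
) -> tuple[int, np.ndarray]:
    """Count resolvable local maxima in the image.

    The image is Gaussian-smoothed (sigma 0.5 px, the module-wide
    pre-measurement convention) and maxima above ``threshold_frac`` of the
    smoothed global maximum with pairwise separation of at least
    ``min_separation_mm`` are counted.  Returns the count and the peak
    coordinates in plane mm, ordered brightest first.
    """
    from scipy.ndimage import gaussian_filter

    img = np.asarray(recon.image, dtype=float)
    if smooth_sigma_px > 0:
        img = gaussian_filter(img, smooth_sigma_px)
    if img.max() <= 0:
        return 0, np.empty((0, 2))
    # conservative square footprint (Chebyshev <= Euclidean); the exact
    # Euclidean separation rule is enforced below
    min_px = max(int(np.floor(min_separation_mm / np.sqrt(2.0)
                              / recon.pixel_size)), 1)
    coords = peak_local_max(
        img, min_distance=min_px,
        threshold_abs=threshold_frac * img.max(),
        exclude_border=False,
    )
    # enforce Euclidean (not Chebyshev) separation, keeping brighter peaks
    vals = img[tuple(coords.T)]
    order = np.argsort(-vals)
    kept: list[np.ndarray] = []
    for k in order:
        c = coords[k]
        if all(np.linalg.norm((c - other) * recon.pixel_size)
               >= min_separation_mm for other in kept):
            kept.append(c)
    plane_coords = np.array([recon.to_plane(int(i), int(j)) for i, j in kept])
    return len(kept), plane_coords.reshape(-1, 2)


@dataclass
class QualityReport:
    """Collected image-quality numbers for one reconstruction."""

    fwhm_mm: dict[tuple[float, float], float | None] = field(default_factory=dict)
    snr_db: dict[tuple[float, float], float] = field(default_factory=dict)
    n_peaks: int = 0
    peak_coords: np.ndarray | None = None

    @property
    def fwhm_values(self) -> np.ndarray:
        return np.array([v for v in self.fwhm_mm.values() if v is not None])

    def summary(self) -> dict:
        out: dict = {"n_peaks": int(self.n_peaks)}
        if self.fwhm_mm:
            vals = self.fwhm_values
            out["fwhm_mean_mm"] = float(vals.mean()) if len(vals) else None
            out["fwhm_sd_mm"] = float(vals.std()) if len(vals) else None
            out["fwhm_undefined"] = sum(v is None for v in self.fwhm_mm.values())
        if self.snr_db:
            out["snr_db"] = {str(k): v for k, v in self.snr_db.items()}
        return out
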