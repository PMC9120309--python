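"""LOR formation, (rho, theta) sinogram binning and SART reconstruction.

Each coincidence yields a line of response (LOR) joining the two predicted
scintillation positions (world mm).  LORs are projected onto a coordinate
plane — by default the chip plane y-z, the plane containing the point-grid
and sphere phantoms — and parametrized by the signed distance ``rho`` of
the line from the origin and the angle ``theta`` in [0, pi) of the line's
in-plane normal.  The 400 x 400 (rho, theta) histogram is reconstructed
with five iterations of SART (scikit-image implementation: bilinear
projector, relaxation 0.15).

Image convention: pixel (i, j) of the reconstructed 400 x 400 image maps
to in-plane coordinates a = (j - 200) * px, b = (200 - i) * px with
px = 2R / 400 mm, matching scikit-image's rotation-center convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import iradon_sart, radon

__all__ = [
    "LOR",
    "Sinogram",
    "ReconImage",
    "PLANE_AXES",
    "lor_to_rho_theta",
    "build_sinogram",
    "sart_reconstruct",
    "forward_project",
]

PLANE_AXES = {"yz": (1, 2), "xy": (0, 1), "xz": (0, 2)}

DEFAULT_R = 40.0  # mm, rho half-range; covers the chip with margin
DEFAULT_BINS = 400
DEGENERATE_TOL = 1e-6  # mm, endpoints closer than this in-plane are dropped


@dataclass(frozen=True)
class LOR:
    """One coincidence line of response between two detectors."""

    endpoint_a: np.ndarray  # world mm
    endpoint_b: np.ndarray
    event_id: int = -1


@dataclass
class Sinogram:
    """(rho, theta) LOR histogram: rows rho, columns theta."""

    counts: np.ndarray  # (bins, bins)
    rho_edges: np.ndarray  # mm
    theta_centers_deg: np.ndarray
    plane: str
    n_dropped: int = 0

    @property
    def pixel_size(self) -> float:
        return float(self.rho_edges[1] - self.rho_edges[0])


@dataclass
class ReconImage:
    """Reconstructed 2D image on one coordinate plane."""

    image: np.ndarray  # (bins, bins)
    pixel_size: float  # mm
    plane: str

    def to_pixel(self, a: float, b: float) -> tuple[int, int]:
        """In-plane (a, b) mm -> (row, col) pixel indices."""
        c = self.image.shape[0] // 2
        return (int(round(c - b / self.pixel_size)),
                int(round(c + a / self.pixel_size)))

    def to_plane(self, i: int, j: int) -> tuple[float, float]:
        c = self.image.shape[0] // 2
        return ((j - c) * self.pixel_size, (c - i) * self.pixel_size)


def _project(points: np.ndarray, plane: str) -> np.ndarray:
    try:
        ia, ib = PLANE_AXES[plane]
    except KeyError:
        raise ValueError(f"unknown plane {plane!r}; choose from {sorted(PLANE_AXES)}")
    return np.asarray(points, dtype=float)[..., [ia, ib]]


def lor_to_rho_theta(lor: LOR, plane: str = "yz") -> tuple[float, float]:
    """Signed distance (mm) and normal angle (rad, [0, pi)) of one LOR.

    The LOR endpoints are projected onto the plane; theta is the angle of
    the in-plane unit normal n = (cos theta, sin theta) and
    rho = p . n for any point p on the line.  Raises ValueError for
    degenerate (coincident) projections.
    """
    p1 = _project(lor.endpoint_a, plane)
    p2 = _project(lor.endpoint_b, plane)
    rho, theta, ok = _rho_theta_arrays(p1[None, :], p2[None, :])
    if not ok[0]:
        raise ValueError("degenerate LOR projection")
    return float(rho[0]), float(theta[0])


def _rho_theta_arrays(p1: np.ndarray, p2: np.ndarray):
    d = p2 - p1
    norm = np.linalg.norm(d, axis=1)
    ok = norm > DEGENERATE_TOL
    safe = np.where(ok, norm, 1.0)
    u = d / safe[:, None]
    normal = np.column_stack([-u[:, 1], u[:, 0]])
    theta = np.arctan2(normal[:, 1], normal[:, 0])
    rho = np.einsum("ij,ij->i", p1, normal)
    flip_lo = theta < 0
    theta = np.where(flip_lo, theta + np.pi, theta)
    rho = np.where(flip_lo, -rho, rho)
    flip_hi = theta >= np.pi  # theta == pi lands back at 0
    theta = np.where(flip_hi, theta - np.pi, theta)
    rho = np.where(flip_hi, -rho, rho)
    return rho, theta, ok


def build_sinogram(
    lors: list[LOR] | tuple[np.ndarray, np.ndarray],
    plane: str = "yz",
    rho_max: float = DEFAULT_R,
    bins: int = DEFAULT_BINS,
) -> Sinogram:
    """Histogram LORs into the (rho, theta) sinogram.

    ``lors`` may be a list of :class:`LOR` or a pair of (N, 3) endpoint
    arrays.  Out-of-range rho and degenerate projections are dropped and
    counted in ``n_dropped``.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if isinstance(lors, tuple):
        ends_a, ends_b = (np.asarray(e, dtype=float) for e in lors)
    else:
        ends_a = np.array([l.endpoint_a for l in lors], dtype=float).reshape(-1, 3)
        ends_b = np.array([l.endpoint_b for l in lors], dtype=float).reshape(-1, 3)
    px = 2.0 * rho_max / bins
    # bin i is centred on rho = (i - bins//2) * px, aligning rho = 0 with
    # scikit-image's rotation-centre pixel
    rho_edges = (np.arange(bins + 1) - bins // 2 - 0.5) * px
    theta_edges = np.linspace(0.0, np.pi, bins + 1)
    if len(ends_a) == 0:
        counts = np.zeros((bins, bins))
    else:
        p1 = _project(ends_a, plane)
        p2 = _project(ends_b, plane)
        rho, theta, ok = _rho_theta_arrays(p1, p2)
        in_range = ok & (rho >= rho_edges[0]) & (rho < rho_edges[-1])
        counts, _, _ = np.histogram2d(
            rho[in_range], np.clip(theta[in_range], 0.0, np.pi - 1e-12),
            bins=[rho_edges, theta_edges],
        )
    n_total = len(ends_a)
    n_kept = int(counts.sum())
    theta_centers = np.rad2deg(0.5 * (theta_edges[:-1] + theta_edges[1:]))
    return Sinogram(
        counts=counts,
        rho_edges=rho_edges,
        theta_centers_deg=theta_centers,
        plane=plane,
        n_dropped=n_total - n_kept,
    )


def forward_project(image: np.ndarray, sinogram_like: Sinogram) -> np.ndarray:
    """Radon transform of an image on the sinogram's (rho, theta) grid."""
    return radon(image, theta=sinogram_like.theta_centers_deg)


def sart_reconstruct(
    sinogram: Sinogram,
    iterations: int = 5,
    relaxation: float = 0.15,
) -> ReconImage:
    """Reconstruct the plane image with SART.

    Runs ``iterations`` full sweeps of scikit-image's SART (bilinear
    projector) at the given relaxation factor.  An all-zero sinogram
    yields an all-zero image.
    """
    counts = np.asarray(sinogram.counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("sinogram counts must be non-negative")
    if not counts.any():
        return ReconImage(np.zeros_like(counts), sinogram.pixel_size,
                          sinogram.plane)
    theta = sinogram.theta_centers_deg
    image = None
    for _ in range(iterations):
        image = iradon_sart(counts, theta=theta, image=image,
                            relaxation=relaxation)
    return ReconImage(image, sinogram.pixel_size, sinogram.plane)
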