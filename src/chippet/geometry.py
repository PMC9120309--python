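"""Scanner geometry: four monolithic-crystal detectors around a square bore.

The scanner consists of four box-shaped detectors arranged at 90 degree
intervals about the axial (z) axis.  Each detector holds two LYSO crystals
stacked along z inside a 0.1 mm epoxy envelope, and carries SiPM channel
grids on five of its six surfaces (the bore-facing front surface is bare).

Coordinate conventions
----------------------
World frame: z is the scanner axis, the bore cross-section lies in the x-y
plane, the origin is the scanner center.

Detector-local frame (per detector): ``x`` tangential in [0, 52.2] mm,
``y`` the depth coordinate in [0, thickness] mm with y = 0 on the
bore-facing front surface, ``z`` axial in [0, 104.4] mm.  Detector ``d``
is detector 0 rotated by ``d * 90`` degrees about the world z axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CrystalSpec",
    "DetectorSpec",
    "SurfaceGrid",
    "FrameTransform",
    "ScannerGeometry",
    "build_scanner",
    "surface_grids",
    "SIPM_PITCH_FACTOR",
    "SURFACE_NAMES",
]

#: Channel pitch over nominal SiPM size.  The per-surface channel counts of
#: the 26.1 mm detector (back 16x32, left/right 8x32, top/bottom 16x8 for
#: 3 mm SiPMs) imply a pitch of surface_length / count = 3.2625 mm, i.e.
#: 1.0875 times the nominal photosensitive-area size; the same factor
#: reproduces the 4 mm and 6 mm counts.
SIPM_PITCH_FACTOR = 1.0875

SURFACE_NAMES = ("back", "left", "right", "top", "bottom")

VALID_THICKNESSES = (13.0, 26.0)
VALID_SIPM_SIZES = (3.0, 4.0, 6.0)

EPOXY_MARGIN = 0.1  # mm of epoxy on every crystal face
BORE_HALF_WIDTH = 26.1  # mm, radial distance of each front face
SCANNER_BOX = 114.8  # mm, bounding box that all four detectors fit in


class ConfigurationError(ValueError):
    """Raised for geometry parameters outside the supported design space."""


@dataclass(frozen=True)
class CrystalSpec:
    """One monolithic LYSO block (52 x thickness x 52 mm)."""

    width_x: float = 52.0
    thickness_y: float = 13.0
    length_z: float = 52.0

    def __post_init__(self) -> None:
        if self.thickness_y not in VALID_THICKNESSES:
            raise ConfigurationError(
                f"crystal thickness must be one of {VALID_THICKNESSES} mm, "
                f"got {self.thickness_y}"
            )
        if self.width_x != 52.0 or self.length_z != 52.0:
            raise ConfigurationError("crystal cross-section is fixed at 52 x 52 mm")


@dataclass(frozen=True)
class DetectorSpec:
    """Two crystals stacked along z inside a 0.1 mm epoxy envelope.

    The epoxy glues the crystals to the SiPMs, so it wraps every surface
    except the bare bore-facing front one: the detector box measures
    52.2 x (thickness + 0.1) x 104.4 mm, with the crystal front face flush
    with the detector front face (local y = 0).
    """

    crystal: CrystalSpec = field(default_factory=CrystalSpec)
    epoxy_margin: float = EPOXY_MARGIN

    @property
    def size_x(self) -> float:
        return self.crystal.width_x + 2 * self.epoxy_margin

    @property
    def size_y(self) -> float:
        return self.crystal.thickness_y + self.epoxy_margin

    @property
    def size_z(self) -> float:
        return 2 * (self.crystal.length_z + 2 * self.epoxy_margin)

    def crystal_bounds_local(self) -> list[np.ndarray]:
        """Axis-aligned bounds of the two crystals in the detector frame.

        Returns a list of two (2, 3) arrays [[xmin, ymin, zmin],
        [xmax, ymax, zmax]] in mm.  The epoxy margin is excluded: gamma
        interactions are only scored inside LYSO.
        """
        m = self.epoxy_margin
        c = self.crystal
        out = []
        for k in range(2):
            z0 = k * (c.length_z + 2 * m) + m
            out.append(
                np.array(
                    [[m, 0.0, z0], [m + c.width_x, c.thickness_y, z0 + c.length_z]]
                )
            )
        return out


def _rotz(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class FrameTransform:
    """Rigid map local = R @ world + t (and its inverse)."""

    rotation: np.ndarray
    translation: np.ndarray

    def world_to_local(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def local_to_world(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - self.translation) @ self.rotation

    def rotate_world_to_local(self, vec: np.ndarray) -> np.ndarray:
        return np.asarray(vec, dtype=float) @ self.rotation.T

    def rotate_local_to_world(self, vec: np.ndarray) -> np.ndarray:
        return np.asarray(vec, dtype=float) @ self.rotation


def _detector_transform(det_id: int, detector: DetectorSpec) -> FrameTransform:
    # Detector 0 occupies world x in [26.1, 26.1 + size_y]; its local frame is
    #   x_l = -w_y + size_x/2, y_l = w_x - bore_half_width, z_l = w_z + size_z/2
    # a proper rotation (about z) plus translation.  Detector d first rotates
    # the world point by -d*90 deg about z into detector 0's frame.
    base_rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    rot = base_rot @ _rotz(-90.0 * det_id)
    trans = np.array([detector.size_x / 2.0, -BORE_HALF_WIDTH, detector.size_z / 2.0])
    return FrameTransform(rotation=rot, translation=trans)


@dataclass(frozen=True)
class SurfaceGrid:
    """SiPM channel grid on one instrumented detector surface.

    Channel centers are given in surface-local (u, v) mm, u and v being the
    two in-plane detector-local axes of that surface.  The grid is centered
    on the surface: n = floor(L / pitch) channels per axis with
    pitch = 1.0875 * sipm_size.
    """

    surface_name: str
    dim_u: float
    dim_v: float
    sipm_size: float
    pitch: float
    n_u: int
    n_v: int
    centers_u: np.ndarray
    centers_v: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.n_u * self.n_v


def _make_grid(name: str, dim_u: float, dim_v: float, sipm_size: float) -> SurfaceGrid:
    pitch = SIPM_PITCH_FACTOR * sipm_size
    n_u = int(np.floor(dim_u / pitch + 1e-9))
    n_v = int(np.floor(dim_v / pitch + 1e-9))
    margin_u = (dim_u - n_u * pitch) / 2.0
    margin_v = (dim_v - n_v * pitch) / 2.0
    centers_u = margin_u + pitch * (np.arange(n_u) + 0.5)
    centers_v = margin_v + pitch * (np.arange(n_v) + 0.5)
    return SurfaceGrid(
        surface_name=name,
        dim_u=dim_u,
        dim_v=dim_v,
        sipm_size=sipm_size,
        pitch=pitch,
        n_u=n_u,
        n_v=n_v,
        centers_u=centers_u,
        centers_v=centers_v,
    )


def surface_grids(detector: DetectorSpec, sipm_size: float) -> dict[str, SurfaceGrid]:
    """Lay out SiPM grids on the five instrumented surfaces.

    Surface (u, v) axes in the detector-local frame:

    ========  ==================  ==========
    surface   plane               (u, v)
    ========  ==================  ==========
    back      y = size_y          (x, z)
    left      x = 0               (y, z)
    right     x = size_x          (y, z)
    top       z = size_z          (x, y)
    bottom    z = 0               (x, y)
    ========  ==================  ==========
    """
    if float(sipm_size) not in VALID_SIPM_SIZES:
        raise ConfigurationError(
            f"SiPM size must be one of {VALID_SIPM_SIZES} mm, got {sipm_size}"
        )
    sx, sy, sz = detector.size_x, detector.size_y, detector.size_z
    return {
        "back": _make_grid("back", sx, sz, sipm_size),
        "left": _make_grid("left", sy, sz, sipm_size),
        "right": _make_grid("right", sy, sz, sipm_size),
        "top": _make_grid("top", sx, sy, sipm_size),
        "bottom": _make_grid("bottom", sx, sy, sipm_size),
    }


@dataclass(frozen=True)
class ScannerGeometry:
    """The full four-detector scanner."""

    detector: DetectorSpec
    transforms: tuple[FrameTransform, ...]
    bore_half_width: float = BORE_HALF_WIDTH

    @property
    def n_detectors(self) -> int:
        return len(self.transforms)

    @property
    def crystal_thickness(self) -> float:
        return self.detector.crystal.thickness_y

    def world_to_detector(self, points: np.ndarray, det_id: int) -> np.ndarray:
        return self.transforms[det_id].world_to_local(points)

    def detector_to_world(self, points: np.ndarray, det_id: int) -> np.ndarray:
        return self.transforms[det_id].local_to_world(points)

    def crystal_bounds_world(self) -> list[tuple[int, np.ndarray, np.ndarray]]:
        """All eight crystals as (det_id, rotation, local bounds) records."""
        out = []
        for d, tf in enumerate(self.transforms):
            for bounds in self.detector.crystal_bounds_local():
                out.append((d, tf, bounds))
        return out


def build_scanner(thickness_y: float = 13.0) -> ScannerGeometry:
    """Build the scanner for a given crystal thickness (13 or 26 mm).

    The four detector front faces sit at radial distance 26.1 mm from the
    axis and tile a closed square bore of side 52.2 mm; everything fits in
    the 114.8 mm scanner bounding box.
    """
    detector = DetectorSpec(crystal=CrystalSpec(thickness_y=float(thickness_y)))
    transforms = tuple(_detector_transform(d, detector) for d in range(4))
    geom = ScannerGeometry(detector=detector, transforms=transforms)
    # sanity: every detector stays inside the scanner bounding box
    extent = max(BORE_HALF_WIDTH + detector.size_y, detector.size_x / 2.0,
                 detector.size_z / 2.0)
    assert 2 * extent <= SCANNER_BOX
    return geom
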