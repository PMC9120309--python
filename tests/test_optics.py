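"""Scintillation light model and SiPM response."""

import numpy as np
import pytest

from chippet.geometry import CrystalSpec, DetectorSpec
from chippet.optics import (PADDED_SIZES, ScintillatorSpec, SiPMSpec,
                            SurfaceOptics, distribute_photons,
                            make_pattern_set, photon_yield, rect_solid_angle,
                            sipm_response)
from chippet.transport import GammaInteraction

DET13 = DetectorSpec(crystal=CrystalSpec(thickness_y=13.0))


def test_photon_yield_statistics():
    rng = np.random.default_rng(0)
    spec = ScintillatorSpec()
    draws = np.array([photon_yield(0.511, spec, rng) for _ in range(10_000)])
    mean = 40_000 * 0.511  # 20,440 photons expected at 511 keV
    assert draws.mean() == pytest.approx(mean, rel=0.005)
    assert draws.std() == pytest.approx(4.8 * np.sqrt(mean), rel=0.05)


def test_photon_yield_degenerate_resolution():
    rng = np.random.default_rng(1)
    spec = ScintillatorSpec(resolution_scale=1.0)
    draws = {photon_yield(0.511, spec, rng) for _ in range(50)}
    assert all(abs(d - 20_440) < 4 * np.sqrt(20_440) for d in draws)


def test_solid_angle_matches_monte_carlo():
    # pitch-square patch at 6.5 mm, normal incidence, vs a ray-shooting MC
    half = 3.2625 / 2.0
    d = 6.5
    exact = rect_solid_angle(-half, half, -half, half, d) / (4 * np.pi)
    rng = np.random.default_rng(2)
    n = 4_000_000
    u = rng.uniform(-1, 1, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - u**2)
    dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), u])
    up = dirs[:, 2] > 1e-12
    t = d / dirs[up, 2]
    xy = dirs[up, :2] * t[:, None]
    frac = (np.abs(xy) <= half).all(axis=1).mean() * up.mean()
    assert exact == pytest.approx(frac, rel=0.01)


def test_solid_angle_completeness_over_enclosing_box():
    # patches tiling all six faces of a box subtend 4*pi from any interior
    # point (bulk absorption off, escape cone off)
    point = np.array([2.0, 7.0, 4.0])
    L, n = 10.0, 8
    h = L / n
    total = 0.0
    for axis in range(3):
        ua, va = [a for a in range(3) if a != axis]
        for plane in (0.0, L):
            dist = abs(point[axis] - plane)
            edges = np.arange(n + 1) * h
            for i in range(n):
                for j in range(n):
                    total += rect_solid_angle(
                        edges[i] - point[ua], edges[i + 1] - point[ua],
                        edges[j] - point[va], edges[j + 1] - point[va], dist)
    assert total / (4 * np.pi) == pytest.approx(1.0, abs=1e-3)


def test_channel_weights_sum_to_one_without_cone_for_full_box():
    # the five instrumented surfaces plus the front almost tile the
    # detector box; compare sum of weights vs the front-face solid angle
    optics = SurfaceOptics(DET13, 3.0,
                           scintillator=ScintillatorSpec(absorption_length=1e12),
                           escape_cone_enabled=False)
    point = np.array([26.1, 6.5, 52.2])
    w = optics.weights(point)
    total = sum(v.sum() for v in w.values())
    # front face solid angle from the point
    front = rect_solid_angle(-26.1, 26.1, -52.2, 52.2, 6.5) / (4 * np.pi)
    # grids leave uninstrumented margins; the sum must stay below the
    # tiling bound and approach it within those margins
    assert total < 1.0 - front
    assert total > 0.85 * (1.0 - front)


def test_center_channel_outweighs_edge_channel():
    optics = SurfaceOptics(DET13, 3.0)
    point = np.array([26.1, 6.5, 52.2])
    grid = optics.grids["back"]
    w = optics.weights(point)["back"].reshape(grid.n_u, grid.n_v)
    center = w[grid.n_u // 2, grid.n_v // 2]
    assert center > w[0, 0]


def test_photon_distribution_conserves_and_matches_weights():
    optics = SurfaceOptics(DET13, 3.0)
    rng = np.random.default_rng(3)
    weights = optics.weights(np.array([20.0, 5.0, 40.0]))
    arrivals, escaped = distribute_photons(100_000, weights, rng)
    total = sum(a.sum() for a in arrivals.values()) + escaped
    assert total == 100_000
    flat_w = np.concatenate([weights[k] for k in weights])
    flat_a = np.concatenate([arrivals[k] for k in arrivals])
    # empirical fractions within 5 sigma of multinomial expectation
    exp = 100_000 * flat_w
    sd = np.sqrt(np.maximum(100_000 * flat_w * (1 - flat_w), 1e-12))
    big = exp > 50
    assert np.all(np.abs(flat_a[big] - exp[big]) < 5 * sd[big])
    arrivals0, escaped0 = distribute_photons(0, weights, rng)
    assert escaped0 == 0 and all(a.sum() == 0 for a in arrivals0.values())


def test_sipm_response_zero_and_expectation():
    rng = np.random.default_rng(4)
    quiet = SiPMSpec.for_size(3.0, dark_count_rate=0.0)
    assert np.all(sipm_response(np.zeros(10, dtype=int), quiet, rng) == 0)
    # expectation before saturation: arrivals*PDE*fill*(1+ct)*(1+ap) + dark
    spec = SiPMSpec.for_size(3.0)
    big_pix = SiPMSpec.for_size(3.0, pixels_per_channel=10**9)
    arrivals = np.full(20_000, 200)
    out = sipm_response(arrivals, big_pix, rng)
    pitch = 1.0875 * 3.0
    expected = 200 * 0.5 * 0.74 * 1.07 * 1.06 + spec.dark_mean(pitch)
    assert out.mean() == pytest.approx(expected, rel=0.01)


def test_sipm_saturation_limit():
    rng = np.random.default_rng(5)
    spec = SiPMSpec.for_size(3.0)
    out = sipm_response(np.array([10**7]), spec, rng)
    assert out[0] == pytest.approx(3531, rel=1e-3)


@pytest.mark.parametrize("sipm, size", [(3.0, 32), (4.0, 24), (6.0, 16)])
def test_padded_pattern_sizes(sipm, size):
    assert PADDED_SIZES[sipm] == size
    optics = SurfaceOptics(DET13, sipm)
    rng = np.random.default_rng(6)
    inter = GammaInteraction(0, 0, np.zeros(3), np.array([26.0, 6.0, 52.0]),
                             0.0)
    ps = make_pattern_set(inter, optics, SiPMSpec.for_size(sipm),
                          ScintillatorSpec(), rng)
    for pat in ps.patterns.values():
        assert pat.padded.shape == (size, size)
        assert np.all(pat.padded[~pat.mask] == 0)
        # padding preserves the raw values bit-exactly
        assert np.array_equal(pat.padded[pat.mask].reshape(pat.raw.shape),
                              pat.raw)


def test_pattern_argmax_tracks_interaction_point():
    optics = SurfaceOptics(DET13, 3.0)
    rng = np.random.default_rng(7)
    truth = np.array([20.0, 6.0, 60.0])
    inter = GammaInteraction(0, 0, np.zeros(3), truth, 0.0)
    ps = make_pattern_set(inter, optics, SiPMSpec.for_size(3.0),
                          ScintillatorSpec(), rng)
    grid = optics.grids["back"]
    iu, iv = np.unravel_index(ps.patterns["back"].raw.argmax(),
                              ps.patterns["back"].raw.shape)
    assert abs(grid.centers_u[iu] - truth[0]) <= 2 * grid.pitch
    assert abs(grid.centers_v[iv] - truth[2]) <= 2 * grid.pitch


def test_back_intensity_decreases_with_distance_from_back():
    # expected (deterministic) back-surface light fraction falls as the
    # interaction moves away from the back surface; with the escape cone
    # the drop is absorption-driven, without it solid-angle driven
    for cone in (True, False):
        optics = SurfaceOptics(DET13, 3.0, escape_cone_enabled=cone)
        totals = []
        for depth in (12.0, 9.0, 6.5, 4.0, 1.0):  # back surface at y = 13.1
            w = optics.weights(np.array([26.1, depth, 52.2]))
            totals.append(w["back"].sum())
        assert all(a > b for a, b in zip(totals, totals[1:]))


def test_pattern_generation_deterministic_under_seed():
    optics = SurfaceOptics(DET13, 3.0)
    inter = GammaInteraction(0, 0, np.zeros(3), np.array([26.0, 6.0, 52.0]),
                             0.0)
    outs = []
    for _ in range(2):
        rng = np.random.default_rng(9)
        ps = make_pattern_set(inter, optics, SiPMSpec.for_size(3.0),
                              ScintillatorSpec(), rng)
        outs.append(np.stack([p.padded for p in ps.patterns.values()]))
    assert np.array_equal(outs[0], outs[1])
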