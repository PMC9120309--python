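"""Gamma transport: annihilation, crystal tracing, coincidence sorting."""

import numpy as np
import pytest
from scipy import stats

from chippet.geometry import build_scanner
from chippet.phantoms import DecayEvent, line_source
from chippet.transport import (GammaInteraction, PhysicsOptions, annihilate,
                               annihilate_batch, sensitivity,
                               simulate_decays, sort_coincidences,
                               trace_gamma, trace_gamma_batch)

BARE = PhysicsOptions(positron_range_enabled=False,
                      acollinearity_enabled=False,
                      phantom_attenuation_enabled=False)


def test_annihilation_exact_back_to_back_with_options_off():
    rng = np.random.default_rng(0)
    decay = DecayEvent(0, np.array([1.0, 2.0, 3.0]), 0.0)
    point, d1, d2 = annihilate(decay, BARE, rng)
    np.testing.assert_allclose(point, decay.position)
    np.testing.assert_allclose(d1, -d2, atol=1e-12)
    assert np.linalg.norm(d1) == pytest.approx(1.0)


def test_positron_range_mean_displacement():
    rng = np.random.default_rng(1)
    opts = PhysicsOptions(acollinearity_enabled=False)
    pts, _, _ = annihilate_batch(np.zeros((100_000, 3)), opts, rng)
    mags = np.linalg.norm(pts, axis=1)
    assert mags.mean() == pytest.approx(0.6, abs=0.01)


def test_gamma_directions_isotropic():
    rng = np.random.default_rng(2)
    _, d1, _ = annihilate_batch(np.zeros((100_000, 3)), BARE, rng)
    np.testing.assert_allclose(d1.mean(axis=0), 0.0, atol=0.01)
    # uniform cos(theta)
    _, p = stats.kstest(d1[:, 2], stats.uniform(loc=-1, scale=2).cdf)
    assert p > 1e-3


def test_axial_ray_escapes():
    rng = np.random.default_rng(3)
    geom = build_scanner(13.0)
    hit = trace_gamma(np.zeros(3), np.array([0.0, 0.0, 1.0]), geom, BARE, rng)
    assert hit is None


def test_perpendicular_interaction_probability_closed_form():
    # chord through 13 mm of LYSO at mu = 0.87/cm: p = 1 - exp(-1.131)
    rng = np.random.default_rng(4)
    geom = build_scanner(13.0)
    n = 40_000
    # z = 10: transaxial rays at z = 0 run inside the inter-crystal epoxy
    origins = np.tile([0.0, 0.0, 10.0], (n, 1))
    dirs = np.tile([1.0, 0.0, 0.0], (n, 1))
    hit, det, pts, _ = trace_gamma_batch(origins, dirs, geom, BARE, rng)
    expected = 1.0 - np.exp(-0.087 * 13.0)
    assert expected == pytest.approx(0.677, abs=0.001)
    se = np.sqrt(expected * (1 - expected) / n)
    assert hit.mean() == pytest.approx(expected, abs=4 * se)
    assert set(det[hit]) == {0}


def test_interaction_depth_follows_truncated_exponential():
    rng = np.random.default_rng(5)
    geom = build_scanner(13.0)
    n = 100_000
    origins = np.tile([0.0, 0.0, 10.0], (n, 1))
    dirs = np.tile([1.0, 0.0, 0.0], (n, 1))
    hit, _, pts, _ = trace_gamma_batch(origins, dirs, geom, BARE, rng)
    depth = pts[hit, 0] - 26.1
    mu = 0.087
    chord = 13.0
    trunc = stats.truncexpon(b=mu * chord, scale=1.0 / mu)
    _, p = stats.kstest(depth, trunc.cdf)
    assert p > 1e-3


def test_interactions_confined_to_crystal_volume(scanner13):
    rng = np.random.default_rng(6)
    src = line_source()
    from chippet.phantoms import sample_decays
    decays = sample_decays(src, seed=rng, n_events=4_000)
    inter = simulate_decays(decays, scanner13, PhysicsOptions(), rng, src)
    assert len(inter) > 0
    for g in inter[:500]:
        x, y, z = g.position_local
        assert 0.1 - 1e-9 <= x <= 52.1 + 1e-9
        assert -1e-9 <= y <= 13.0 + 1e-9
        assert 0.1 - 1e-9 <= z <= 104.3 + 1e-9
        assert not (52.1 < z < 52.3)  # inter-crystal epoxy gap


def _interaction(eid, det, t):
    return GammaInteraction(eid, det, np.zeros(3), np.zeros(3), t)


def test_coincidence_sorting_rules():
    # opposing detectors -> one true; same detector -> singles only
    trues, randoms, singles = sort_coincidences(
        [_interaction(0, 0, 0.0), _interaction(0, 2, 1e-12)])
    assert (len(trues), randoms, singles) == (1, 0, 0)
    trues, randoms, singles = sort_coincidences(
        [_interaction(0, 0, 0.0), _interaction(0, 0, 1e-12)])
    assert (len(trues), randoms, singles) == (0, 0, 2)
    # different decays inside the window are randoms; window 0 disables
    pair = [_interaction(0, 0, 0.0), _interaction(1, 1, 2e-9)]
    assert sort_coincidences(pair, window_ns=10.0)[1] == 1
    assert sort_coincidences(pair, window_ns=0.0)[1] == 0


def test_sensitivity_monotone_in_thickness_and_mu(scanner13, scanner26):
    src = line_source()
    s13 = sensitivity(src, scanner13, n_events=6_000, seed=7)
    s26 = sensitivity(src, scanner26, n_events=6_000, seed=7)
    assert s26 > s13
    values = [
        sensitivity(src, scanner13, PhysicsOptions(mu_lyso_511=mu),
                    n_events=6_000, seed=8)
        for mu in (0.3, 0.87, 2.0)
    ]
    assert values[0] < values[1] < values[2]


def test_sensitivity_vanishes_without_attenuation(scanner13):
    opts = PhysicsOptions(mu_lyso_511=1e-6,
                          phantom_attenuation_enabled=False)
    assert sensitivity(line_source(), scanner13, opts,
                       n_events=4_000, seed=9) < 0.005


def test_high_mu_limit_matches_geometric_acceptance(scanner13):
    # mu -> inf: every gamma entering a crystal interacts, so sensitivity
    # equals the fraction of decays whose both gammas cross some crystal
    rng = np.random.default_rng(10)
    src = line_source()
    from chippet.phantoms import sample_decays
    from chippet.transport import _crystal_segments
    decays = sample_decays(src, seed=rng, n_events=6_000)
    opts = PhysicsOptions(mu_lyso_511=1e4,
                          phantom_attenuation_enabled=False,
                          positron_range_enabled=False,
                          acollinearity_enabled=False)
    pos = np.array([d.position for d in decays])
    pts, d1, d2 = annihilate_batch(pos, opts, np.random.default_rng(11))
    both = np.ones(len(pts), dtype=bool)
    dets = []
    for dirs in (d1, d2):
        t_in, t_out, det_ids = _crystal_segments(scanner13, pts, dirs)
        chords = t_out - t_in
        both &= chords.sum(axis=1) > 0
        first = np.argmin(np.where(chords > 0, t_in, np.inf), axis=1)
        dets.append(det_ids[first])
    geometric = (both & (dets[0] != dets[1])).mean()
    measured = sensitivity(src, scanner13, opts, n_events=6_000, seed=10)
    assert measured == pytest.approx(geometric, abs=0.02)


def test_zero_decays_raise(scanner13):
    with pytest.raises(ValueError):
        sensitivity(line_source(), scanner13, duration=0.0, n_events=None,
                    seed=0)
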