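"""Centroiding baseline, CNN contract and error metrics."""

import numpy as np
import pytest

from chippet.estimators import (CnnConfig, CnnRegressor, centroid_predict,
                                evaluate, parse_subset, surface_subsets)
from chippet.geometry import SURFACE_NAMES, CrystalSpec, DetectorSpec
from chippet.optics import (LightPattern, LightPatternSet, ScintillatorSpec,
                            SiPMSpec, SurfaceOptics, make_pattern_set)
from chippet.transport import GammaInteraction

DET13 = DetectorSpec(crystal=CrystalSpec(thickness_y=13.0))


def _pattern_set(optics, fill):
    """Build a LightPatternSet by calling ``fill(name, grid) -> raw``."""
    patterns = {}
    size = 32
    for name, grid in optics.grids.items():
        raw = fill(name, grid)
        from chippet.optics import _pad_square
        padded, mask = _pad_square(raw, size)
        patterns[name] = LightPattern(name, raw, padded, mask)
    return LightPatternSet(0, 0, patterns, np.zeros(3))


def test_single_channel_patterns_recover_channel_centers():
    optics = SurfaceOptics(DET13, 3.0)
    # one lit channel per surface, all consistent with one 3D point
    target_idx = {"back": (5, 10), "left": (2, 10), "right": (2, 10),
                  "top": (5, 2), "bottom": (5, 2)}

    def fill(name, grid):
        raw = np.zeros((grid.n_u, grid.n_v))
        raw[target_idx[name]] = 7.0
        return raw

    ps = _pattern_set(optics, fill)
    pred = centroid_predict(ps, optics)
    back = optics.grids["back"]
    left = optics.grids["left"]
    top = optics.grids["top"]
    expected = np.array([
        (back.centers_u[5] + top.centers_u[5]) / 2.0,
        (left.centers_u[2] + top.centers_v[2]) / 2.0,
        (back.centers_v[10] + left.centers_v[10]) / 2.0,
    ])
    np.testing.assert_allclose(pred, expected, atol=1e-12)


def test_symmetric_patterns_predict_detector_center():
    optics = SurfaceOptics(DET13, 3.0)
    ps = _pattern_set(optics, lambda name, grid: np.ones((grid.n_u,
                                                          grid.n_v)))
    pred = centroid_predict(ps, optics)
    det = optics.detector
    np.testing.assert_allclose(
        pred, [det.size_x / 2, det.size_y / 2, det.size_z / 2], atol=1e-9)


def test_all_zero_patterns_raise():
    optics = SurfaceOptics(DET13, 3.0)
    ps = _pattern_set(optics, lambda name, grid: np.zeros((grid.n_u,
                                                           grid.n_v)))
    with pytest.raises(ValueError, match="empty"):
        centroid_predict(ps, optics)


def _centroid_oracle(ps, optics):
    """Literal step-by-step reimplementation of the centroiding recipe.

    Shares no helpers with the production path: (1) image-moment centroid
    per pattern, (2) paired-surface means, (3) per-dimension means,
    (4) stack.
    """
    cen = {}
    for name, pat in ps.patterns.items():
        grid = optics.grids[name]
        m = pat.raw
        total = m.sum()
        if total <= 0:
            continue
        uu, vv = np.meshgrid(grid.centers_u, grid.centers_v, indexing="ij")
        cen[name] = ((m * uu).sum() / total, (m * vv).sum() / total)
    planes = {}
    if "top" in cen or "bottom" in cen:
        pair = [cen[n] for n in ("top", "bottom") if n in cen]
        planes["xy"] = tuple(np.mean(pair, axis=0))
    if "left" in cen or "right" in cen:
        pair = [cen[n] for n in ("left", "right") if n in cen]
        planes["yz"] = tuple(np.mean(pair, axis=0))
    if "back" in cen:
        planes["xz"] = cen["back"]
    x = np.mean([planes[p][0] for p in ("xy", "xz") if p in planes])
    y = np.mean([v for v in (
        planes.get("xy", (None, None))[1],
        planes.get("yz", (None, None))[0]) if v is not None])
    z = np.mean([planes[p][1] for p in ("xz", "yz") if p in planes])
    return np.array([x, y, z])


def test_centroid_pipeline_matches_stepwise_oracle():
    optics = SurfaceOptics(DET13, 3.0)
    sipm = SiPMSpec.for_size(3.0)
    scint = ScintillatorSpec()
    rng = np.random.default_rng(0)
    for _ in range(25):
        truth = np.array([rng.uniform(1, 51), rng.uniform(0.5, 12.5),
                          rng.uniform(1, 103)])
        ps = make_pattern_set(GammaInteraction(0, 0, np.zeros(3), truth, 0.0),
                              optics, sipm, scint, rng)
        np.testing.assert_allclose(centroid_predict(ps, optics),
                                   _centroid_oracle(ps, optics), atol=1e-9)


def test_centroid_stays_inside_detector_box():
    optics = SurfaceOptics(DET13, 3.0)
    sipm = SiPMSpec.for_size(3.0)
    scint = ScintillatorSpec()
    rng = np.random.default_rng(1)
    det = optics.detector
    for _ in range(20):
        truth = np.array([rng.uniform(0.2, 52), rng.uniform(0, 13),
                          rng.uniform(0.2, 104)])
        ps = make_pattern_set(GammaInteraction(0, 0, np.zeros(3), truth, 0.0),
                              optics, sipm, scint, rng)
        pred = centroid_predict(ps, optics)
        assert 0 <= pred[0] <= det.size_x
        assert 0 <= pred[1] <= det.size_y
        assert 0 <= pred[2] <= det.size_z


def test_subset_parsing_and_enumeration():
    assert parse_subset("ba-le-ri") == ("back", "left", "right")
    assert parse_subset("BO") == ("bottom",)
    assert len(surface_subsets()) == 31
    with pytest.raises(ValueError):
        parse_subset("xx")
    with pytest.raises(ValueError):
        parse_subset("")


def test_untrained_model_output_contract():
    model = CnnRegressor(5, 16, CnnConfig(steps=10), seed=0)
    out = model.predict(np.zeros((2, 5, 16, 16), dtype=np.float32))
    assert out.shape == (2, 3)
    with pytest.raises(ValueError):
        from chippet.estimators import train_cnn
        train_cnn(np.zeros((4, 5, 16, 8)), np.zeros((4, 3)))


def test_evaluate_closed_forms():
    rng = np.random.default_rng(2)
    truth = np.column_stack([rng.uniform(0, 52, 100),
                             rng.uniform(0, 13, 100),
                             rng.uniform(0, 104, 100)])
    perfect = evaluate(truth, truth, 13.0)
    assert perfect.mae == 0.0 and perfect.mean_euclidean == 0.0
    shifted = evaluate(truth + 1.0, truth, 13.0)
    assert shifted.mae == pytest.approx(1.0)
    assert shifted.mean_euclidean == pytest.approx(np.sqrt(3.0))


@pytest.mark.parametrize("thickness, n_bins", [(13.0, 4), (26.0, 8)])
def test_depth_bin_count(thickness, n_bins):
    truth = np.column_stack([np.full(50, 26.0),
                             np.linspace(0.1, thickness - 0.1, 50),
                             np.full(50, 52.0)])
    res = evaluate(truth, truth, thickness)
    assert len(res.depth_bin_error) == n_bins
    assert res.depth_bin_edges[-1] == pytest.approx(thickness)


def test_empty_split_rejected():
    with pytest.raises(ValueError):
        evaluate(np.empty((0, 3)), np.empty((0, 3)))
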