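"""Shared fixtures: scanners, optics stacks and simulated sample sets.

The expensive artifacts (simulated datasets, the trained CNN, the
end-to-end grid reconstruction) are session-scoped so the whole suite
pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from chippet.dataset import DatasetConfig, generate_samples, split
from chippet.estimators import (CnnConfig, centroid_predict_batch, evaluate,
                                train_cnn)
from chippet.geometry import build_scanner
from chippet.optics import SurfaceOptics, pattern_sets_from_padded


def _collect(config: DatasetConfig):
    pats, poss = [], []
    for p, pos, _eid, _det, _nc in generate_samples(config):
        pats.append(p)
        poss.append(pos)
    return np.concatenate(pats), np.concatenate(poss)


@pytest.fixture(scope="session")
def scanner13():
    return build_scanner(13.0)


@pytest.fixture(scope="session")
def scanner26():
    return build_scanner(26.0)


@pytest.fixture(scope="session")
def optics6(scanner13):
    return SurfaceOptics(scanner13.detector, 6.0)


@pytest.fixture(scope="session")
def box_samples_13(scanner13, optics6):
    """Simulated box-phantom samples, 13 mm crystals, 6 mm SiPMs.

    Returns a dict with raw and peak-normalized pattern stacks, truth
    positions, train/val split indices and the centroid-baseline result.
    """
    X, Y = _collect(DatasetConfig(phantom="box", n_decays=8_000,
                                  sipm_size=6.0, seed=3))
    peak = X.reshape(len(X), -1).max(axis=1)
    Xn = (X / np.maximum(peak, 1e-12)[:, None, None, None]).astype(np.float32)
    idx = split(len(X), {"train": 0.8, "val": 0.2}, seed=0)
    sets = pattern_sets_from_padded(X, Y, optics6)
    centroid = evaluate(centroid_predict_batch(sets, optics6), Y, 13.0)
    return {"X": X, "Xn": Xn, "Y": Y, "split": idx, "centroid": centroid}


@pytest.fixture(scope="session")
def box_samples_26(scanner26):
    """Smaller 26 mm companion set for the thickness comparison."""
    X, Y = _collect(DatasetConfig(phantom="box", n_decays=4_000,
                                  crystal_thickness=26.0, sipm_size=6.0,
                                  seed=4))
    optics = SurfaceOptics(scanner26.detector, 6.0)
    sets = pattern_sets_from_padded(X, Y, optics)
    centroid = evaluate(centroid_predict_batch(sets, optics), Y, 26.0)
    return {"X": X, "Y": Y, "centroid": centroid}


@pytest.fixture(scope="session")
def trained_cnn(box_samples_13):
    """CNN trained on the scaled box-phantom profile (all five surfaces)."""
    d = box_samples_13
    tr, va = d["split"]["train"], d["split"]["val"]
    model = train_cnn(d["Xn"][tr], d["Y"][tr], d["Xn"][va], d["Y"][va],
                      config=CnnConfig(steps=2_000, eval_interval=250),
                      seed=0)
    return model


@pytest.fixture(scope="session")
def grid_run():
    """End-to-end grid-phantom reconstruction with the centroid estimator."""
    from chippet.pipeline import RunConfig, run_pipeline

    return run_pipeline(RunConfig(phantom="grid21", n_decays=50_000, seed=0))
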