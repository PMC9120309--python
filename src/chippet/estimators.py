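"""First-interaction position estimators.

Two estimators map a detector's five surface light patterns to the 3D
scintillation position in detector-local mm:

* :func:`centroid_predict` — the classic centroiding baseline.  Each
  pattern's intensity-weighted centroid gives two local coordinates;
  paired surfaces are averaged, then each coordinate is averaged over the
  planes that constrain it.
* :class:`CnnRegressor` — a compact convolutional network trained on the
  stacked (C, S, S) patterns with MAE loss and Adam (learning rate 3e-4,
  batch 256), where C is the number of input surfaces.

Error reporting follows two conventions: "MAE" is the mean over samples
and the three coordinates of the absolute error; "positioning error" is
the mean Euclidean distance.  Depth-resolved errors use 3.25 mm bins of
the local depth coordinate (4 bins for 13 mm crystals, 8 for 26 mm).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import _nn
from .geometry import SURFACE_NAMES
from .optics import LightPatternSet, SurfaceOptics

__all__ = [
    "SURFACE_ABBREV",
    "parse_subset",
    "surface_subsets",
    "centroid_predict",
    "centroid_predict_batch",
    "CnnConfig",
    "CnnRegressor",
    "train_cnn",
    "PredictionResult",
    "evaluate",
    "DEPTH_BIN_WIDTH",
]

DEPTH_BIN_WIDTH = 3.25  # mm

SURFACE_ABBREV = {"ba": "back", "le": "left", "ri": "right", "to": "top",
                  "bo": "bottom"}

# surface -> the two detector-local axes its pattern constrains
_SURFACE_AXES = {
    "back": (0, 2),   # (x, z)
    "left": (1, 2),   # (y, z)
    "right": (1, 2),
    "top": (0, 1),    # (x, y)
    "bottom": (0, 1),
}


def parse_subset(spec: str | tuple[str, ...]) -> tuple[str, ...]:
    """Normalize a surface subset given as names or 'ba-le-ri' abbreviations."""
    if isinstance(spec, str):
        parts = spec.replace(",", "-").split("-")
    else:
        parts = list(spec)
    out = []
    for p in parts:
        p = p.strip().lower()
        name = SURFACE_ABBREV.get(p[:2], p) if p not in SURFACE_NAMES else p
        if name not in SURFACE_NAMES:
            raise ValueError(f"unknown surface {p!r}")
        out.append(name)
    if not out:
        raise ValueError("surface subset must be nonempty")
    return tuple(dict.fromkeys(out))


def surface_subsets() -> list[tuple[str, ...]]:
    """All 31 nonempty surface combinations, largest first."""
    subs = []
    for k in range(5, 0, -1):
        subs.extend(itertools.combinations(SURFACE_NAMES, k))
    return subs


# ---------------------------------------------------------------------------
# centroiding baseline


def _surface_centroid(raw: np.ndarray, grid) -> tuple[float, float] | None:
    total = raw.sum()
    if total <= 0:
        return None
    u = float((raw.sum(axis=1) * grid.centers_u).sum() / total)
    v = float((raw.sum(axis=0) * grid.centers_v).sum() / total)
    return u, v


def centroid_predict(
    pattern_set: LightPatternSet,
    optics: SurfaceOptics,
    surfaces: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Centroiding baseline position estimate in detector-local mm.

    (1) intensity-weighted centroid of each pattern (valid channels only);
    (2) average paired-surface centroids: left+right -> (y, z),
    top+bottom -> (x, y), back alone -> (x, z); (3) average each
    coordinate over the planes that provide it; (4) stack to (x, y, z).
    All-zero patterns are excluded from their plane's average.
    """
    surfaces = surfaces or tuple(pattern_set.patterns)
    plane_centroids: dict[tuple[int, int], list[np.ndarray]] = {}
    for name in surfaces:
        pat = pattern_set.patterns.get(name)
        if pat is None:
            continue
        cen = _surface_centroid(pat.raw, optics.grids[name])
        if cen is None:
            continue
        axes = _SURFACE_AXES[name]
        plane_centroids.setdefault(axes, []).append(np.array(cen))
    if not plane_centroids:
        raise ValueError("all light patterns are empty; centroid undefined")
    coords: dict[int, list[float]] = {}
    for axes, cens in plane_centroids.items():
        mean_cen = np.mean(cens, axis=0)
        for axis, value in zip(axes, mean_cen):
            coords.setdefault(axis, []).append(float(value))
    center = np.array([optics.detector.size_x, optics.detector.size_y,
                       optics.detector.size_z]) / 2.0
    return np.array([
        np.mean(coords[a]) if a in coords else center[a] for a in range(3)
    ])


def centroid_predict_batch(
    pattern_sets: list[LightPatternSet],
    optics: SurfaceOptics,
    surfaces: tuple[str, ...] | None = None,
) -> np.ndarray:
    return np.array([centroid_predict(ps, optics, surfaces)
                     for ps in pattern_sets])


# ---------------------------------------------------------------------------
# CNN regressor


@dataclass
class CnnConfig:
    """Training protocol for the convolutional position regressor."""

    channels: tuple[int, ...] = (16, 32, 32)  # conv widths; stride 2 after 1st
    hidden: int = 64
    learning_rate: float = 3e-4
    batch_size: int = 256
    steps: int = 5_000
    eval_interval: int = 250
    loss: str = "mae"

    def __post_init__(self) -> None:
        if self.steps <= 0:
            raise ValueError("step budget must be positive")


class CnnRegressor:
    """Small CNN mapping stacked light patterns to a 3D position.

    Input (N, C, S, S) float patterns (normalized per set to peak 1);
    output 3 detector-local coordinates in mm.  Targets are internally
    standardized to the crystal half-dimensions so every coordinate
    contributes comparably to the MAE loss.
    """

    def __init__(self, n_channels: int, image_size: int,
                 config: CnnConfig | None = None, seed: int = 0):
        self.config = config or CnnConfig()
        self.n_channels = n_channels
        self.image_size = image_size
        rng = np.random.default_rng(seed)
        cfg = self.config
        layers: list[_nn.Layer] = []
        c_prev = n_channels
        for i, c in enumerate(cfg.channels):
            stride = 1 if i == 0 else 2
            layers += [_nn.Conv2d(c_prev, c, 3, stride, 1, rng), _nn.ReLU()]
            c_prev = c
        layers += [_nn.GlobalAvgPool(),
                   _nn.Linear(c_prev, cfg.hidden, rng), _nn.ReLU(),
                   _nn.Linear(cfg.hidden, 3, rng)]
        self.net = _nn.Sequential(layers)
        self.target_center = np.zeros(3)
        self.target_scale = np.ones(3)
        self.history: dict[str, list] = {"step": [], "train_mae": [],
                                         "val_mae": []}

    def _encode(self, y: np.ndarray) -> np.ndarray:
        return (y - self.target_center) / self.target_scale

    def _decode(self, y: np.ndarray) -> np.ndarray:
        return y * self.target_scale + self.target_center

    def predict(self, x: np.ndarray, batch: int = 1024) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        outs = [self.net.forward(x[i:i + batch], train=False)
                for i in range(0, len(x), batch)]
        return self._decode(np.concatenate(outs))

    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        seed: int = 0,
        verbose: bool = False,
    ) -> "CnnRegressor":
        cfg = self.config
        rng = np.random.default_rng(seed)
        y_train = np.asarray(y_train, dtype=float)
        self.target_center = y_train.mean(axis=0)
        self.target_scale = np.maximum(y_train.std(axis=0), 1e-6)
        yt = self._encode(y_train)
        opt = _nn.Adam(self.net.params, lr=cfg.learning_rate)
        n = len(x_train)
        for step in range(1, cfg.steps + 1):
            idx = rng.integers(0, n, size=min(cfg.batch_size, n))
            xb = np.asarray(x_train[idx], dtype=np.float32)
            pred = self.net.forward(xb, train=True)
            loss, grad = _nn.mae_loss(pred, yt[idx])
            self.net.backward(grad)
            opt.step(self.net.grads)
            if step % cfg.eval_interval == 0 or step == cfg.steps:
                train_mae = loss * self.target_scale.mean()  # approx mm scale
                rec = {"step": step, "train_mae": float(train_mae)}
                if x_val is not None:
                    val_pred = self.predict(x_val)
                    val_mae = float(np.abs(val_pred - y_val).mean())
                    rec["val_mae"] = val_mae
                self.history["step"].append(step)
                self.history["train_mae"].append(rec["train_mae"])
                self.history["val_mae"].append(rec.get("val_mae", np.nan))
                if verbose:
                    print("  step %6d  train %.3f  val %.3f"
                          % (step, rec["train_mae"], rec.get("val_mae", np.nan)))
        return self

    # -- checkpointing ------------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "params": [p.copy() for p in self.net.params],
            "target_center": self.target_center.copy(),
            "target_scale": self.target_scale.copy(),
            "n_channels": self.n_channels,
            "image_size": self.image_size,
        }

    def load_state_dict(self, state: dict) -> None:
        for p, saved in zip(self.net.params, state["params"]):
            p[...] = saved
        self.target_center = np.asarray(state["target_center"])
        self.target_scale = np.asarray(state["target_scale"])


def train_cnn(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    config: CnnConfig | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> CnnRegressor:
    """Train the convolutional regressor on stacked patterns.

    ``x_train`` has shape (N, C, S, S): C input surfaces stacked along the
    channel axis over S x S padded patterns.
    """
    x_train = np.asarray(x_train)
    if x_train.ndim != 4 or x_train.shape[2] != x_train.shape[3]:
        raise ValueError("patterns must be (N, C, S, S) with square images")
    model = CnnRegressor(x_train.shape[1], x_train.shape[2], config, seed)
    model.fit(x_train, y_train, x_val, y_val, seed=seed + 1, verbose=verbose)
    return model


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class PredictionResult:
    """Aggregate error report of an estimator on one dataset split."""

    predictions: np.ndarray
    truths: np.ndarray
    mae: float  # mean over samples and the 3 coordinates of |error|, mm
    mae_per_axis: np.ndarray
    mean_euclidean: float  # mean positioning error, mm
    depth_bin_edges: np.ndarray
    depth_bin_error: np.ndarray  # mean Euclidean error per depth bin
    depth_bin_counts: np.ndarray

    def error_heatmap(self, depth_bin: int | None = None, bins: int = 16,
                      extent: tuple[float, float] = (0.0, 104.4)
                      ) -> np.ndarray:
        """Mean positioning error over the (x, z) plane, optionally for one
        depth bin; NaN where a cell holds no samples."""
        err = np.linalg.norm(self.predictions - self.truths, axis=1)
        sel = np.ones(len(err), dtype=bool)
        if depth_bin is not None:
            lo = self.depth_bin_edges[depth_bin]
            hi = self.depth_bin_edges[depth_bin + 1]
            depth = self.truths[:, 1]
            sel = (depth >= lo) & (depth < hi)
        x, z = self.truths[sel, 0], self.truths[sel, 2]
        sums, xe, ze = np.histogram2d(
            x, z, bins=bins, range=[(0.0, 52.2), extent], weights=err[sel])
        counts, _, _ = np.histogram2d(x, z, bins=bins,
                                      range=[(0.0, 52.2), extent])
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def evaluate(predictions: np.ndarray, truths: np.ndarray,
             crystal_thickness: float = 13.0) -> PredictionResult:
    """Error metrics for predicted vs true detector-local positions."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if len(predictions) == 0:
        raise ValueError("empty evaluation split")
    abs_err = np.abs(predictions - truths)
    eucl = np.linalg.norm(predictions - truths, axis=1)
    n_bins = int(round(crystal_thickness / DEPTH_BIN_WIDTH))
    edges = DEPTH_BIN_WIDTH * np.arange(n_bins + 1)
    depth = truths[:, 1]
    which = np.clip(np.digitize(depth, edges) - 1, 0, n_bins - 1)
    bin_err = np.zeros(n_bins)
    bin_cnt = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = which == b
        bin_cnt[b] = mask.sum()
        bin_err[b] = eucl[mask].mean() if bin_cnt[b] else np.nan
    return PredictionResult(
        predictions=predictions,
        truths=truths,
        mae=float(abs_err.mean()),
        mae_per_axis=abs_err.mean(axis=0),
        mean_euclidean=float(eucl.mean()),
        depth_bin_edges=edges,
        depth_bin_error=bin_err,
        depth_bin_counts=bin_cnt,
    )
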