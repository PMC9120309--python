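"""Training/evaluation dataset construction and split bookkeeping.

A dataset row is one (light-pattern stack, ground-truth local position)
pair.  Each simulated decay contributes zero, one or two rows: one per
detector in which a gamma interacted (singles included — a row needs no
coincidence partner).  Rows are streamed into an HDF5 container:

    /samples/patterns   (N, 5, S, S) float32, raw channel outputs, padded
    /samples/positions  (N, 3) float64, detector-local mm
    /samples/event_id   (N,) int64
    /samples/det_id     (N,) int8
    /meta               attrs: phantom, thickness, sipm size, seed, counts

with a JSON manifest sidecar that records everything needed to regenerate
the file bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .geometry import SURFACE_NAMES, build_scanner
from .optics import (PADDED_SIZES, ScintillatorSpec, SiPMSpec, SurfaceOptics,
                     make_pattern_set)
from .phantoms import SourceModel, make_source, sample_decays
from .transport import PhysicsOptions, simulate_decays

__all__ = [
    "DatasetConfig",
    "DatasetManifest",
    "generate_samples",
    "build_dataset",
    "load_dataset",
    "split",
]


@dataclass(frozen=True)
class DatasetConfig:
    """Everything that determines a dataset's content."""

    phantom: str = "box"
    n_decays: int = 10_000
    crystal_thickness: float = 13.0
    sipm_size: float = 3.0
    seed: int = 0
    chunk_decays: int = 2_000
    reflection_boost: float = 1.0


@dataclass
class DatasetManifest:
    config: DatasetConfig
    n_samples: int
    n_decays: int
    n_coincidences: int
    padded_size: int
    splits: dict | None = None

    def to_json(self) -> str:
        d = {"config": asdict(self.config), "n_samples": self.n_samples,
             "n_decays": self.n_decays, "n_coincidences": self.n_coincidences,
             "padded_size": self.padded_size, "splits": self.splits}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        d = json.loads(text)
        return cls(config=DatasetConfig(**d["config"]),
                   n_samples=d["n_samples"], n_decays=d["n_decays"],
                   n_coincidences=d["n_coincidences"],
                   padded_size=d["padded_size"], splits=d.get("splits"))


def _sim_stack(config: DatasetConfig):
    geometry = build_scanner(config.crystal_thickness)
    source = make_source(config.phantom)
    optics = SurfaceOptics(geometry.detector, config.sipm_size,
                           reflection_boost=config.reflection_boost)
    sipm = SiPMSpec.for_size(config.sipm_size)
    scint = ScintillatorSpec()
    return geometry, source, optics, sipm, scint


def generate_samples(config: DatasetConfig, physics: PhysicsOptions | None = None):
    """Yield (patterns, positions, event_ids, det_ids, n_coinc) chunks.

    Decays are simulated in chunks of ``config.chunk_decays``; every
    interaction (coincident or single) becomes one sample.
    """
    geometry, source, optics, sipm, scint = _sim_stack(config)
    physics = physics or PhysicsOptions()
    rng = np.random.default_rng(config.seed)
    size = PADDED_SIZES[config.sipm_size]
    done = 0
    next_event = 0
    while done < config.n_decays:
        n = min(config.chunk_decays, config.n_decays - done)
        decays = sample_decays(source, seed=rng, n_events=n)
        decays = [type(d)(d.event_id + next_event, d.position, d.time)
                  for d in decays]
        next_event += n
        interactions = simulate_decays(decays, geometry, physics, rng, source)
        m = len(interactions)
        patterns = np.zeros((m, 5, size, size), dtype=np.float32)
        positions = np.zeros((m, 3))
        event_ids = np.zeros(m, dtype=np.int64)
        det_ids = np.zeros(m, dtype=np.int8)
        for k, inter in enumerate(interactions):
            ps = make_pattern_set(inter, optics, sipm, scint, rng)
            for c, name in enumerate(SURFACE_NAMES):
                patterns[k, c] = ps.patterns[name].padded
            positions[k] = ps.truth_local
            event_ids[k] = inter.event_id
            det_ids[k] = inter.det_id
        _, counts = np.unique(event_ids, return_counts=True)
        n_coinc = int((counts == 2).sum())  # upper bound: same-detector pairs rare
        done += n
        yield patterns, positions, event_ids, det_ids, n_coinc


def build_dataset(path: str | Path, config: DatasetConfig,
                  physics: PhysicsOptions | None = None) -> DatasetManifest:
    """Simulate and write a dataset container; returns its manifest."""
    import h5py

    if config.n_decays <= 0:
        raise ValueError("n_decays must be positive")
    path = Path(path)
    size = PADDED_SIZES[config.sipm_size]
    n_total = 0
    n_coinc = 0
    try:
        with h5py.File(path, "w") as f:
            grp = f.create_group("samples")
            d_pat = grp.create_dataset(
                "patterns", shape=(0, 5, size, size),
                maxshape=(None, 5, size, size), dtype="f4",
                chunks=(256, 5, size, size))
            d_pos = grp.create_dataset("positions", shape=(0, 3),
                                       maxshape=(None, 3), dtype="f8")
            d_eid = grp.create_dataset("event_id", shape=(0,),
                                       maxshape=(None,), dtype="i8")
            d_det = grp.create_dataset("det_id", shape=(0,),
                                       maxshape=(None,), dtype="i1")
            for patterns, positions, eids, dets, nc in generate_samples(
                    config, physics):
                m = len(patterns)
                for dset, arr in ((d_pat, patterns), (d_pos, positions),
                                  (d_eid, eids), (d_det, dets)):
                    dset.resize(n_total + m, axis=0)
                    dset[n_total:n_total + m] = arr
                n_total += m
                n_coinc += nc
            meta = f.create_group("meta")
            for key, value in asdict(config).items():
                meta.attrs[key] = value
            meta.attrs["n_samples"] = n_total
            meta.attrs["n_coincidences"] = n_coinc
    except Exception:
        path.unlink(missing_ok=True)  # no partial files
        raise
    manifest = DatasetManifest(config=config, n_samples=n_total,
                               n_decays=config.n_decays,
                               n_coincidences=n_coinc, padded_size=size)
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        manifest.to_json())
    return manifest


def load_dataset(path: str | Path, in_memory: bool = True):
    """Read back a dataset container as a dict of arrays."""
    import h5py

    with h5py.File(path, "r") as f:
        out = {
            "patterns": f["samples/patterns"][:],
            "positions": f["samples/positions"][:],
            "event_id": f["samples/event_id"][:],
            "det_id": f["samples/det_id"][:],
            "meta": dict(f["meta"].attrs),
        }
    return out


def split(n_samples: int, fractions: dict[str, float],
          seed: int = 0) -> dict[str, np.ndarray]:
    """Disjoint, seed-stable index sets, e.g. {"train": .8, "val": .2}."""
    total = sum(fractions.values())
    if total > 1.0 + 1e-9:
        raise ValueError("split fractions must sum to at most 1")
    if any(f < 0 for f in fractions.values()):
        raise ValueError("split fractions must be non-negative")
    perm = np.random.default_rng(seed).permutation(n_samples)
    out = {}
    start = 0
    for name, frac in fractions.items():
        k = int(round(frac * n_samples))
        out[name] = np.sort(perm[start:start + k])
        start += k
    return out
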