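"""End-to-end orchestration: decays -> patterns -> positions -> image.

The full chain mirrors how the scanner would be used: simulate positron
decays of a phantom, transport the annihilation gammas into the crystals,
form coincidences, simulate the SiPM light patterns of both interactions,
estimate the scintillation positions, build LORs in world coordinates, bin
the (rho, theta) sinogram and reconstruct with SART.

Randomness is organized as named substreams spawned from one master seed
(decay, transport, optics, training) so stages are independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .estimators import CnnRegressor, centroid_predict
from .geometry import SURFACE_NAMES, build_scanner
from .optics import (ScintillatorSpec, SiPMSpec, SurfaceOptics,
                     make_pattern_set)
from .phantoms import make_source, sample_decays
from .reconstruction import ReconImage, Sinogram, build_sinogram, sart_reconstruct
from .transport import PhysicsOptions, simulate_decays, sort_coincidences

__all__ = ["RunConfig", "RunResult", "substreams", "predict_lors",
           "run_pipeline"]


def substreams(seed: int, names: tuple[str, ...] = ("decay", "transport",
                                                    "optics", "training")):
    """Named, independent random generators fanned out from one seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class RunConfig:
    """Single-file description of a full pipeline run."""

    phantom: str = "grid21"
    n_decays: int = 50_000
    crystal_thickness: float = 13.0
    sipm_size: float = 3.0
    estimator: str = "centroid"  # or "cnn" with a checkpoint via model=
    plane: str = "yz"
    rho_max: float = 40.0
    bins: int = 400
    sart_iterations: int = 5
    sart_relaxation: float = 0.15
    seed: int = 0
    chunk_decays: int = 5_000
    physics: PhysicsOptions = field(default_factory=PhysicsOptions)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunResult:
    config: RunConfig
    sinogram: Sinogram
    image: ReconImage
    endpoints_a: np.ndarray
    endpoints_b: np.ndarray
    counts: dict

    @property
    def n_lors(self) -> int:
        return len(self.endpoints_a)


def predict_lors(
    config: RunConfig,
    model: CnnRegressor | None = None,
    rngs: dict | None = None,
    progress: bool = False,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate decays and return predicted LOR endpoint arrays (world mm).

    For every true coincidence the two interactions' light patterns are
    simulated and fed to the position estimator; the detector-local
    predictions are mapped back to world coordinates as LOR endpoints.
    Returns (endpoints_a, endpoints_b, stage counts).
    """
    geometry = build_scanner(config.crystal_thickness)
    source = make_source(config.phantom)
    optics = SurfaceOptics(geometry.detector, config.sipm_size)
    sipm = SiPMSpec.for_size(config.sipm_size)
    scint = ScintillatorSpec()
    rngs = rngs or substreams(config.seed)

    counts = {"decays": 0, "interactions": 0, "coincidences": 0,
              "randoms": 0, "singles": 0}
    ends_a: list[np.ndarray] = []
    ends_b: list[np.ndarray] = []
    done = 0
    next_event = 0
    iterator = range(0, config.n_decays, config.chunk_decays)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(list(iterator), desc="simulating", unit="chunk")
    for _ in iterator:
        n = min(config.chunk_decays, config.n_decays - done)
        decays = sample_decays(source, seed=rngs["decay"], n_events=n)
        decays = [type(d)(d.event_id + next_event, d.position, d.time)
                  for d in decays]
        next_event += n
        done += n
        interactions = simulate_decays(decays, geometry, config.physics,
                                       rngs["transport"], source)
        trues, randoms, singles = sort_coincidences(
            interactions, config.physics.coincidence_window_ns)
        counts["decays"] += n
        counts["interactions"] += len(interactions)
        counts["coincidences"] += len(trues)
        counts["randoms"] += randoms
        counts["singles"] += singles
        for coin in trues:
            pair = []
            for inter in (coin.first, coin.second):
                ps = make_pattern_set(inter, optics, sipm, scint,
                                      rngs["optics"])
                if config.estimator == "centroid":
                    local = centroid_predict(ps, optics)
                elif config.estimator == "cnn":
                    if model is None:
                        raise ValueError("cnn estimator needs a model")
                    x = ps.stacked(SURFACE_NAMES)[None]
                    local = model.predict(x)[0]
                else:
                    raise ValueError(f"unknown estimator {config.estimator!r}")
                pair.append(geometry.detector_to_world(local, inter.det_id))
            ends_a.append(pair[0])
            ends_b.append(pair[1])
    a = np.array(ends_a).reshape(-1, 3)
    b = np.array(ends_b).reshape(-1, 3)
    return a, b, counts


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    model: CnnRegressor | None = None,
    progress: bool = False,
) -> RunResult:
    """Run the full chain and optionally persist artifacts to a directory."""
    ends_a, ends_b, counts = predict_lors(config, model=model,
                                          progress=progress)
    sinogram = build_sinogram((ends_a, ends_b), plane=config.plane,
                              rho_max=config.rho_max, bins=config.bins)
    counts["lors"] = len(ends_a)
    counts["lors_dropped"] = sinogram.n_dropped
    image = sart_reconstruct(sinogram, iterations=config.sart_iterations,
                             relaxation=config.sart_relaxation)
    result = RunResult(config=config, sinogram=sinogram, image=image,
                       endpoints_a=ends_a, endpoints_b=ends_b, counts=counts)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "sinogram.npy", sinogram.counts)
        np.save(out / "image.npy", image.image)
        np.savetxt(out / "lors.csv",
                   np.hstack([ends_a, ends_b]), delimiter=",",
                   header="ax,ay,az,bx,by,bz", comments="")
        (out / "run.json").write_text(json.dumps(
            {"config": config.to_dict(), "counts": counts}, indent=2))
    return result
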