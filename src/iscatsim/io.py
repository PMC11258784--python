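"""Output writing: float TIFF images, far-field containers, run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from .fields import FarField, SphereGrid

__all__ = [
    "write_tiff",
    "read_tiff",
    "save_farfield",
    "load_farfield",
    "RunManifest",
]


def write_tiff(path, intensity: np.ndarray, preview: bool = False):
    """32-bit float TIFF (lossless); optional 8-bit preview alongside."""
    import tifffile

    arr = np.asarray(intensity, dtype=np.float32)
    tifffile.imwrite(str(path), arr)
    if preview:
        lo, hi = float(arr.min()), float(arr.max())
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        tifffile.imwrite(
            str(Path(path).with_suffix(".preview.tiff")),
            ((arr - lo) * scale).astype(np.uint8),
        )


def read_tiff(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(str(path)))


def save_farfield(path, far: FarField):
    """Serialize a structured far field (grid + complex amplitudes)."""
    if far.grid is None:
        raise ValueError("only structured far fields are serializable")
    np.savez(
        str(path),
        theta=far.grid.theta,
        phi=far.grid.phi,
        w_cos=far.grid.w_cos,
        amplitudes=far.amplitudes,
        k=far.k,
        n_medium=far.n_medium,
    )


def load_farfield(path) -> FarField:
    d = np.load(str(path))
    grid = SphereGrid(theta=d["theta"], phi=d["phi"], w_cos=d["w_cos"])
    return FarField.on_grid(
        grid, d["amplitudes"], float(d["k"]), float(d["n_medium"])
    )


class RunManifest:
    """Deterministic record of a simulation run.

    Identical config + seed reproduce bitwise-identical outputs; the
    manifest stores the config hash, software version, seed, per-stage
    timings and the output file list so runs are auditable.
    """

    def __init__(self, config_text: str, seed: int):
        from . import __version__

        self.config_sha256 = hashlib.sha256(config_text.encode()).hexdigest()
        self.version = __version__
        self.seed = int(seed)
        self.timings: dict[str, float] = {}
        self.outputs: list[str] = []
        self._t0: dict[str, float] = {}

    def start(self, stage: str):
        self._t0[stage] = time.perf_counter()

    def stop(self, stage: str):
        self.timings[stage] = round(time.perf_counter() - self._t0.pop(stage), 4)

    def add_output(self, path):
        self.outputs.append(str(path))

    def write(self, path):
        Path(path).write_text(
            json.dumps(
                {
                    "config_sha256": self.config_sha256,
                    "version": self.version,
                    "seed": self.seed,
                    "timings_s": self.timings,
                    "outputs": self.outputs,
                },
                indent=2,
            )
        )
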