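"""YAML/JSON configuration parsing for simulation runs.

A config file describes the layer stack, illumination, optical train,
scatterer, camera sampling and focal planes; :func:`load_config` resolves
it into a :class:`~iscatsim.microscopy.MicroscopeConfig` plus the focal
plane list, applying documented defaults and raising schema errors that
name the offending field path.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .imaging import OpticalTrain, bfp_attenuator, bfp_block, bfp_compose, bfp_waveplate
from .layers import LayerStack, PlaneWaveSpec
from .materials import Material, builtin_material
from .mesh import TriMesh, cube_mesh, dimer, icosphere
from .microscopy import (
    MeshParticleSpec,
    MicroscopeConfig,
    MieSphereSpec,
    PointDipoleSpec,
)

__all__ = ["load_config", "make_mesh", "config_dict_to_microscope", "canonical_dump"]


class ConfigError(ValueError):
    pass


def _need(d: dict, key: str, path: str):
    if key not in d:
        raise ConfigError(f"{path}.{key}: missing required field")
    return d[key]


def _material(entry, path: str) -> Material:
    if isinstance(entry, str):
        try:
            return builtin_material(entry)
        except KeyError as e:
            raise ConfigError(f"{path}: {e}") from None
    if isinstance(entry, dict):
        if "index" in entry:
            idx = entry["index"]
            if isinstance(idx, (list, tuple)):
                idx = complex(idx[0], idx[1])
            return Material(entry.get("name", "custom"), index=idx)
        if "csv" in entry:
            return Material.from_csv(entry.get("name", "table"), entry["csv"])
        if "name" in entry:
            return _material(entry["name"], path)
    raise ConfigError(f"{path}: material must be a name or {{index:|csv:}} mapping")


def _layers(cfg: dict) -> LayerStack:
    entries = _need(cfg, "layers", "config")
    if not isinstance(entries, list) or len(entries) < 2:
        raise ConfigError("config.layers: need a list of at least two media")
    mats, zs, z = [], [], 0.0
    for i, e in enumerate(entries):
        if isinstance(e, str):
            e = {"material": e}
        mats.append(_material(_need(e, "material", f"config.layers[{i}]"),
                              f"config.layers[{i}].material"))
        if i == 0:
            continue
        if i < len(entries) - 1:
            t = e.get("thickness_nm")
            if t is None:
                raise ConfigError(
                    f"config.layers[{i}].thickness_nm: middle layers need a thickness"
                )
            zs.append(z)
            z -= float(t)
        else:
            zs.append(z)
    return LayerStack(tuple(mats), tuple(zs))


def _illumination(cfg: dict) -> PlaneWaveSpec:
    il = _need(cfg, "illumination", "config")
    pol = il.get("polarization", "TM")
    if isinstance(pol, list):
        pol = tuple(complex(c) if not isinstance(c, (list, tuple)) else complex(*c) for c in pol)
    return PlaneWaveSpec(
        wavelength_nm=float(_need(il, "wavelength_nm", "config.illumination")),
        polar_angle_deg=float(il.get("theta_deg", 0.0)),
        azimuth_deg=float(il.get("phi_deg", 0.0)),
        polarization=pol,
        direction=il.get("direction", "up"),
        amplitude=complex(il.get("amplitude", 1.0)),
    )


def _bfp(entries):
    if not entries:
        return None
    parts = []
    for i, e in enumerate(entries):
        t = _need(e, "type", f"config.optics.bfp[{i}]")
        if t == "waveplate":
            parts.append(
                bfp_waveplate(
                    float(e.get("retardance_rad", np.pi / 2)),
                    float(e.get("fast_axis_deg", 45.0)),
                )
            )
        elif t == "attenuator":
            parts.append(bfp_attenuator(complex(_need(e, "t", f"config.optics.bfp[{i}]"))))
        elif t == "block":
            parts.append(
                bfp_block(
                    float(_need(e, "theta_outer_rad", f"config.optics.bfp[{i}]")),
                    float(e.get("theta_inner_rad", 0.0)),
                )
            )
        else:
            raise ConfigError(f"config.optics.bfp[{i}].type: unknown transform {t!r}")
    return bfp_compose(*parts)


def _optics(cfg: dict) -> OpticalTrain:
    op = _need(cfg, "optics", "config")
    NA = float(_need(op, "NA", "config.optics"))
    n = float(op.get("n", 1.5))
    if NA > n:
        raise ConfigError("config.optics.NA: NA exceeds object-side index")
    bfp = _bfp(op.get("bfp"))
    if "magnification" in op:
        return OpticalTrain.from_magnification(
            NA, n, float(op.get("n_prime", 1.0)), float(op["magnification"]), bfp
        )
    return OpticalTrain(
        NA,
        n,
        float(op.get("n_prime", 1.0)),
        float(op.get("f_mm", 1.0)),
        float(op.get("f_prime_mm", 100.0)),
        bfp,
    )


def make_mesh(shape: str, **params):
    """Built-in particle meshes positioned in sample coordinates.

    Shapes: ``sphere`` (diameter_nm, frequency, gap_nm), ``cube``
    (edge_nm, n_per_edge, gap_nm), ``coated_sphere`` (core_diameter_nm,
    coating_nm, frequency, gap_nm) and ``dimer`` (diameter_nm, gap_nm,
    frequency, surface_gap_nm).  ``gap_nm``/``surface_gap_nm`` is the
    particle-substrate separation; all meshes are closed and outward
    oriented.
    """
    gap = float(params.get("gap_nm", params.get("surface_gap_nm", 0.0)))
    if shape == "sphere":
        d = float(params["diameter_nm"])
        m = icosphere(d, int(params.get("frequency", 4)))
        if params.get("volume_correct", True):
            m = m.scaled(((np.pi * d**3 / 6) / m.volume) ** (1 / 3))
        return m.translated([0, 0, gap + d / 2])
    if shape == "cube":
        L = float(params["edge_nm"])
        m = cube_mesh(L, int(params.get("n_per_edge", 5)))
        return m.translated([0, 0, gap + L / 2])
    if shape == "coated_sphere":
        dc = float(params["core_diameter_nm"])
        t = float(params["coating_nm"])
        if t <= 0:
            raise ConfigError("coated_sphere: coating_nm must be positive")
        nu = int(params.get("frequency", 4))
        outer = icosphere(dc + 2 * t, nu).translated([0, 0, gap + dc / 2 + t])
        inner = icosphere(dc, nu).translated([0, 0, gap + dc / 2 + t])
        return [outer, inner]
    if shape == "dimer":
        d = float(params["diameter_nm"])
        g = float(params["gap_nm"])
        m1, m2 = dimer(d, g, int(params.get("frequency", 4)),
                       params.get("axis", (1.0, 0.0, 0.0)))
        z0 = float(params.get("surface_gap_nm", 5.0)) + d / 2
        return [m1.translated([0, 0, z0]), m2.translated([0, 0, z0])]
    raise ConfigError(f"unknown mesh shape {shape!r}")


def _scatterer(cfg: dict):
    sc = cfg.get("scatterer")
    if sc is None:
        return None
    t = _need(sc, "type", "config.scatterer")
    if t == "dipole":
        return PointDipoleSpec(
            position=tuple(sc.get("position_nm", (0.0, 0.0, 0.0))),
            diameter_nm=float(_need(sc, "diameter_nm", "config.scatterer")),
            material=_material(_need(sc, "material", "config.scatterer"),
                               "config.scatterer.material"),
        )
    if t == "sphere":
        return MieSphereSpec(
            position=tuple(sc.get("position_nm", (0.0, 0.0, 0.0))),
            diameter_nm=float(_need(sc, "diameter_nm", "config.scatterer")),
            material=_material(_need(sc, "material", "config.scatterer"),
                               "config.scatterer.material"),
        )
    if t in ("mesh", "cube", "coated_sphere", "dimer"):
        mat = _material(_need(sc, "material", "config.scatterer"),
                        "config.scatterer.material")
        if t == "mesh":
            from .mesh import load_mesh

            meshes = [load_mesh(_need(sc, "path", "config.scatterer"))]
        else:
            params = {k: v for k, v in sc.items() if k not in ("type", "material", "coating_material")}
            m = make_mesh(t, **params)
            meshes = m if isinstance(m, list) else [m]
        if t == "coated_sphere":
            shell = _material(_need(sc, "material", "config.scatterer"),
                              "config.scatterer.material")
            core = _material(_need(sc, "core_material", "config.scatterer"),
                             "config.scatterer.core_material")
            return MeshParticleSpec(tuple(meshes), (shell, core))
        return MeshParticleSpec(tuple(meshes), tuple([mat] * len(meshes)))
    raise ConfigError(f"config.scatterer.type: unknown scatterer {t!r}")


def config_dict_to_microscope(cfg: dict):
    """Resolve a parsed config mapping; returns (MicroscopeConfig, z_focs)."""
    known = {
        "modality", "layers", "illumination", "optics", "image", "scatterer",
        "focal_planes_um", "contrast", "seed", "collection",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    image = cfg.get("image", {})
    coll = cfg.get("collection", {})
    mc = MicroscopeConfig(
        modality=cfg.get("modality", "iscat"),
        stack=_layers(cfg),
        illumination=_illumination(cfg),
        train=_optics(cfg),
        scatterer=_scatterer(cfg),
        fov_nm=float(image.get("fov_um", 4.0)) * 1000.0,
        n_pixels=int(image.get("pixels", 128)),
        n_theta=int(coll.get("n_theta", 50)),
        n_phi=int(coll.get("n_phi", 51)),
        normalized_contrast=bool(cfg.get("contrast", {}).get("normalized", False)),
        seed=int(cfg.get("seed", 0)),
    )
    z_focs = [1000.0 * float(z) for z in cfg.get("focal_planes_um", [0.0])]
    return mc, z_focs


def load_config(path):
    """Load a YAML (or JSON) config file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return config_dict_to_microscope(cfg)


def canonical_dump(cfg: dict) -> str:
    """Deterministic serialization used for config hashing."""
    return json.dumps(cfg, sort_keys=True, default=str)
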