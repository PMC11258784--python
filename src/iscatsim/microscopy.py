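"""Assembly of iSCAT / COBRI / dark-field camera images.

The pipeline mirrors the experiment: a plane wave drives a layer stack
(:mod:`iscatsim.layers`); a scatterer engine (point dipole, Mie sphere or
boundary-element solution) produces the scattered far field in the upper
host medium; the substrate is folded in at the far-field level
(:mod:`iscatsim.interface`); reference and scattered fields are shifted to
the focal plane, rotated onto the detection axis and imaged through the
aplanatic train (:mod:`iscatsim.imaging`).  The camera records
``|E'_ref + E'_sca|^2``; iSCAT contrast maps are the background-subtracted
interference ``I - |E'_ref|^2`` together with the phase between reference
and scattered image fields.

The COBRI modality is the same pipeline with the illumination direction
flipped by 180 degrees and the transmitted beam as the reference;
dark-field drops the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .bem import BEMSolver, BEMSurface
from .dipole import DipoleScatterer, polarizability_sphere
from .fields import (
    ROT_X_180,
    FarField,
    PlaneWaveDecomposition,
    SphereGrid,
)
from .imaging import CameraImage, ImageGrid, OpticalTrain, image_farfield_bessel, image_pwd
from .interface import MieFarFieldSource, corrected_amplitude_below
from .layers import IncidentField, LayerStack, PlaneWaveSpec, incident_field
from .materials import Material
from .mesh import TriMesh, icosphere
from .mie import MieSphere

__all__ = [
    "PointDipoleSpec",
    "MieSphereSpec",
    "MeshParticleSpec",
    "MicroscopeConfig",
    "ContrastMap",
    "simulate_image",
    "iscat_contrast",
    "ipsf",
    "michelson_contrast",
    "brewster_sweep",
    "focus_correlate",
    "partial_coherence",
    "scan_image",
    "add_noise",
    "system_magnification",
]


# ---------------------------------------------------------------------------
# scatterer specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointDipoleSpec:
    """Polarizable-point scatterer (quasistatic sphere polarizability)."""

    position: tuple[float, float, float]
    diameter_nm: float
    material: Material

    def engine(self, stack, wavelength):
        n_host = stack.top.refractive_index(wavelength).real
        alpha = polarizability_sphere(
            self.diameter_nm,
            self.material.permittivity(wavelength),
            n_host**2,
        )
        return DipoleScatterer(self.position, alpha, n_host, wavelength)


@dataclass(frozen=True)
class MieSphereSpec:
    """Exact sphere (Mie) scatterer."""

    position: tuple[float, float, float]
    diameter_nm: float
    material: Material


@dataclass(frozen=True)
class MeshParticleSpec:
    """Arbitrary particle(s) solved with the boundary-element method.

    Meshes are given in sample coordinates (already positioned above the
    interface); the resulting far field is referenced about the interface
    origin.  ``sphere_radius_correction`` rescales sphere-like meshes to
    the equivalent enclosed volume (the solver is then accurate to the
    element-discretization error rather than the facet volume deficit).
    """

    meshes: tuple[TriMesh, ...]
    materials: tuple[Material, ...]

    def __post_init__(self):
        if len(self.meshes) != len(self.materials):
            raise ValueError("one material per mesh required")


ScattererSpec = PointDipoleSpec | MieSphereSpec | MeshParticleSpec


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicroscopeConfig:
    """Complete description of one interference-microscopy simulation."""

    modality: Literal["iscat", "cobri", "darkfield"]
    stack: LayerStack
    illumination: PlaneWaveSpec
    train: OpticalTrain
    scatterer: ScattererSpec | None
    fov_nm: float = 4000.0
    n_pixels: int = 128
    n_theta: int = 50
    n_phi: int = 51
    normalized_contrast: bool = False
    seed: int = 0

    def __post_init__(self):
        up = self.illumination.direction == "up"
        if self.modality == "iscat" and not up:
            raise ValueError("iSCAT illumination must impinge from below (up)")
        if self.modality == "cobri" and up:
            raise ValueError("COBRI illumination must impinge from above (down)")

    @property
    def wavelength(self) -> float:
        return self.illumination.wavelength_nm

    def image_grid(self) -> ImageGrid:
        return ImageGrid.centered(self.fov_nm, self.n_pixels)


@dataclass(frozen=True)
class ContrastMap:
    """Background-subtracted interference and phase maps (per pixel)."""

    grid: ImageGrid
    values: np.ndarray
    phase: np.ndarray
    normalized: bool = False


# ---------------------------------------------------------------------------
# scattered-field engines
# ---------------------------------------------------------------------------

def _upper_drive_components(drv: IncidentField):
    """Plane-wave terms of the driving field in the upper (host) medium."""
    return [c for c in drv.components if c.region == "above"]


def _scattered_source(cfg: MicroscopeConfig, drv: IncidentField):
    """Build the far-field source and its phase-reference convention.

    Returns ``(source, height, lateral)``: ``height`` is the expansion
    height above the interface (0 for origin-referenced sources) and
    ``lateral`` the in-plane offset applied after the interface correction.
    """
    sc = cfg.scatterer
    lam = cfg.wavelength
    if isinstance(sc, PointDipoleSpec):
        dip = sc.engine(cfg.stack, lam)
        src = dip.free_source(drv)
        pos = np.asarray(sc.position, dtype=float)
        return src, pos[2], pos[:2]
    if isinstance(sc, MieSphereSpec):
        n_host = cfg.stack.top.refractive_index(lam).real
        sphere = MieSphere(
            sc.diameter_nm, sc.material.permittivity(lam), n_host**2, lam
        )
        pos = np.asarray(sc.position, dtype=float)
        drives = []
        for c in _upper_drive_components(drv):
            k_hat = np.real(c.k_vec) / np.linalg.norm(np.real(c.k_vec))
            amp_at = c.E0 * np.exp(1j * c.k_vec @ pos)
            drives.append((k_hat, amp_at))
        return MieFarFieldSource(sphere, drives), pos[2], pos[:2]
    if isinstance(sc, MeshParticleSpec):
        n_host = cfg.stack.top.refractive_index(lam).real
        surfaces = [BEMSurface(m, 0, j + 1) for j, m in enumerate(sc.meshes)]
        regions = {0: complex(n_host**2)}
        regions.update(
            {j + 1: m.permittivity(lam) for j, m in enumerate(sc.materials)}
        )
        solver = BEMSolver(surfaces, regions, lam)
        sol = solver.solve(drv)
        return sol.farfield_source(), 0.0, np.zeros(2)
    raise TypeError(f"unsupported scatterer {type(sc).__name__}")


# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------

def _reference_pwd(cfg: MicroscopeConfig, drv: IncidentField) -> PlaneWaveDecomposition:
    """Reference beam below the stack (reflected for iSCAT, transmitted
    for COBRI), origin-referenced."""
    comp = (
        drv.reflected_component()
        if cfg.modality == "iscat"
        else drv.transmitted_component()
    )
    k_vec = np.real(comp.k_vec)
    k = float(np.linalg.norm(k_vec))
    n2 = cfg.stack.bottom.refractive_index(cfg.wavelength).real
    return PlaneWaveDecomposition(
        directions=(k_vec / k)[None, :],
        amplitudes=comp.E0[None, :],
        k=k,
        n_medium=n2,
    )


def _detection_farfield(cfg, src, height, lateral, z_foc) -> FarField:
    """Interface-corrected scattered far field on the detection-axis grid.

    Built directly on the imaging (+z) grid by mapping each direction
    through the 180-degree detection rotation; re-referenced about the
    focal point before imaging.
    """
    lam = cfg.wavelength
    n2 = cfg.stack.bottom.refractive_index(lam).real
    k2 = 2 * np.pi * n2 / lam
    grid = SphereGrid.cap(cfg.train.theta_max, cfg.n_theta, cfg.n_phi, pole="up")
    d_img = grid.directions
    d_phys = d_img @ ROT_X_180.T
    F_phys = corrected_amplitude_below(src, cfg.stack, height, d_phys)
    # lateral particle offset and focal-point re-referencing (sample frame)
    r_ref = np.array([lateral[0], lateral[1], 0.0])
    phase = np.exp(
        -1j * k2 * np.real(d_phys) @ r_ref
        + 1j * k2 * np.real(d_phys) @ np.array([0.0, 0.0, float(z_foc)])
    )
    F_img = (F_phys * phase[..., None]) @ ROT_X_180.T
    return FarField.on_grid(grid, F_img, k2, n2)


def _detection_reference(cfg, drv, z_foc) -> PlaneWaveDecomposition:
    pwd = _reference_pwd(cfg, drv)
    pwd = pwd.shift([0.0, 0.0, -float(z_foc)])   # re-reference about focus
    return pwd.rotate(ROT_X_180)


def simulate_image(cfg: MicroscopeConfig, z_foc: float = 0.0):
    """Simulate one camera frame.

    Returns ``(camera, ref, sca)``: the interference image and the imaged
    reference and scattered fields, all on the object-referred grid.  The
    identity ``camera.intensity == |ref + sca|^2`` holds per pixel by
    construction.
    """
    lam = cfg.wavelength
    n_det = cfg.stack.bottom.refractive_index(lam).real
    if abs(n_det - cfg.train.n) > 1e-9:
        warnings.warn(
            f"object-side index of the train ({cfg.train.n}) does not match "
            f"the detection medium ({n_det})",
            stacklevel=2,
        )
    drv = incident_field(cfg.stack, cfg.illumination)
    grid = cfg.image_grid()
    if cfg.modality == "darkfield" and cfg.scatterer is None:
        raise ValueError("dark-field without a scatterer has no image")
    if cfg.scatterer is not None:
        src, height, lateral = _scattered_source(cfg, drv)
        far = _detection_farfield(cfg, src, height, lateral, z_foc)
        sca = image_farfield_bessel(far, cfg.train, grid)
    else:
        z = np.zeros((cfg.n_pixels, cfg.n_pixels, 2), dtype=complex)
        sca = CameraImage(grid, z)
    if cfg.modality == "darkfield":
        ref = CameraImage(grid, np.zeros_like(sca.field))
    else:
        ref = image_pwd(_detection_reference(cfg, drv, z_foc), cfg.train, grid)
    camera = ref + sca
    return camera, ref, sca


def iscat_contrast(
    camera: CameraImage, ref: CameraImage, normalized: bool = False
) -> ContrastMap:
    """Background-subtracted interference ``I - |E'_ref|^2`` and phase map.

    The normalized variant divides by ``|E'_ref|^2`` and is rejected when
    the reference vanishes (dark-field); use the raw intensity instead.
    """
    I_ref = ref.intensity
    values = camera.intensity - I_ref
    sca_field = camera.field - ref.field
    phase = np.angle(np.einsum("yxc,yxc->yx", ref.field, np.conj(sca_field)))
    if normalized:
        if I_ref.max() <= 0:
            raise ValueError("normalized contrast undefined for a dark reference")
        values = values / I_ref
    return ContrastMap(camera.grid, values, phase, normalized)


def ipsf(cfg: MicroscopeConfig, z_foc: float = 0.0) -> ContrastMap:
    """Interferometric point-spread function (point-dipole scatterer)."""
    if not isinstance(cfg.scatterer, PointDipoleSpec):
        raise ValueError("the iPSF is defined for a point-dipole scatterer")
    camera, ref, _ = simulate_image(cfg, z_foc)
    return iscat_contrast(camera, ref, cfg.normalized_contrast)


def michelson_contrast(intensity) -> float:
    """(I_max - I_min)/(I_max + I_min), bounded in [0, 1]."""
    I = intensity.intensity if isinstance(intensity, CameraImage) else np.asarray(intensity)
    if np.any(I < 0):
        raise ValueError("intensity must be non-negative")
    hi, lo = float(I.max()), float(I.min())
    if hi == 0.0:
        raise ValueError("Michelson contrast undefined for an all-zero image")
    return (hi - lo) / (hi + lo)


def brewster_sweep(cfg: MicroscopeConfig, angles_deg: Sequence[float], z_foc=0.0):
    """iSCAT images (no background subtraction) across incidence angles.

    TM polarization required: at the Brewster angle the reflected reference
    vanishes and the image approaches the dark-field limit, maximizing the
    Michelson contrast.
    """
    if cfg.illumination.jones()[1] == 0:
        raise ValueError("Brewster sweep requires TM illumination")
    out = []
    for th in angles_deg:
        cfg_i = replace(
            cfg, illumination=replace(cfg.illumination, polar_angle_deg=float(th))
        )
        camera, ref, sca = simulate_image(cfg_i, z_foc)
        out.append((float(th), camera, michelson_contrast(camera)))
    return out


def focus_correlate(sim_stack, z_values, query: CameraImage | np.ndarray):
    """Focal-plane estimation by two-dimensional Pearson correlation.

    ``sim_stack``: iterable of images (CameraImage or arrays) simulated at
    ``z_values``; returns ``(z_best, correlations)`` with ties broken
    toward the smallest ``|z|``.
    """
    q = query.intensity if isinstance(query, CameraImage) else np.asarray(query)
    qc = q - q.mean()
    qn = np.linalg.norm(qc)
    if qn == 0:
        raise ValueError("query image has zero variance")
    corr = []
    for img in sim_stack:
        s = img.intensity if isinstance(img, CameraImage) else np.asarray(img)
        sc = s - s.mean()
        sn = np.linalg.norm(sc)
        if sn == 0:
            raise ValueError("stack image has zero variance")
        corr.append(float(np.sum(qc * sc) / (qn * sn)))
    corr = np.asarray(corr)
    z_values = np.asarray(z_values, dtype=float)
    best = np.flatnonzero(corr >= corr.max() - 1e-12)
    z_best = best[np.argmin(np.abs(z_values[best]))]
    return float(z_values[z_best]), corr


def partial_coherence(
    cfg: MicroscopeConfig,
    wavelengths_nm: Sequence[float],
    weights: Sequence[float],
    z_foc: float = 0.0,
) -> np.ndarray:
    """Finite-longitudinal-coherence image: weighted incoherent intensity sum.

    Each wavelength is simulated coherently; the camera intensities are
    summed with the (normalized, non-negative) spectral weights.
    """
    wavelengths = list(wavelengths_nm)
    w = np.asarray(weights, dtype=float)
    if len(wavelengths) == 0:
        raise ValueError("empty spectrum")
    if len(w) != len(wavelengths) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    total = None
    for lam, wi in zip(wavelengths, w):
        cfg_i = replace(
            cfg, illumination=replace(cfg.illumination, wavelength_nm=float(lam))
        )
        camera, _, _ = simulate_image(cfg_i, z_foc)
        total = wi * camera.intensity if total is None else total + wi * camera.intensity
    return total


def scan_image(
    cfg: MicroscopeConfig,
    focused_drive: PlaneWaveDecomposition,
    scan_x: np.ndarray,
    scan_y: np.ndarray,
    pinhole_nm: float | None = None,
    z_foc: float = 0.0,
) -> np.ndarray:
    """Confocal-style scanning: focused excitation stepped across the sample.

    ``focused_drive`` is the focal-field decomposition centred at the
    origin (see :func:`iscatsim.imaging.focus_beam`); for each scan
    position it is shifted, the scattering is recomputed, and the detected
    signal (pinhole-summed camera intensity; default pinhole radius one
    Airy unit) is recorded.  Supported for point-dipole and Mie
    scatterers; mesh (BEM) scatterers work but are slow.
    """
    if isinstance(cfg.scatterer, MeshParticleSpec):
        warnings.warn("BEM scatterer in scanning mode is slow", stacklevel=2)
    if pinhole_nm is None:
        pinhole_nm = 0.61 * cfg.wavelength / cfg.train.NA
    grid = cfg.image_grid()
    X, Y = grid.XY
    pin = (X**2 + Y**2) <= pinhole_nm**2
    drv0 = incident_field(cfg.stack, cfg.illumination)
    out = np.zeros((len(scan_y), len(scan_x)))
    for iy, ys in enumerate(scan_y):
        for ix, xs in enumerate(scan_x):
            drive = focused_drive.shift([float(xs), float(ys), 0.0])

            class _Drive:
                def __init__(self, pwd):
                    self.pwd = pwd

                def fields(self, pts):
                    return self.pwd.fields(pts)

                def electric(self, pts):
                    return self.pwd.evaluate(pts)

            if cfg.scatterer is None:
                camera, ref, sca = simulate_image(cfg, z_foc)
            else:
                src, height, lateral = _scattered_source(cfg, _Drive(drive))
                far = _detection_farfield(cfg, src, height, lateral, z_foc)
                sca = image_farfield_bessel(far, cfg.train, grid)
                if cfg.modality == "darkfield":
                    camera = sca
                else:
                    drv_ref = _detection_reference(cfg, drv0, z_foc)
                    camera = image_pwd(drv_ref, cfg.train, grid) + sca
            out[iy, ix] = float(camera.intensity[pin].sum())
    return out


def add_noise(
    intensity: np.ndarray,
    model: Literal["gaussian", "poisson"] = "gaussian",
    level: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Seeded detector noise for robustness studies (ideal camera otherwise).

    ``gaussian``: additive with sigma = level * I_max.  ``poisson``: shot
    noise with ``1/level**2`` expected photons at the brightest pixel (so
    ``level`` is the relative noise there), rescaled back to intensity
    units.
    """
    rng = np.random.default_rng(seed)
    I = np.asarray(intensity, dtype=float)
    if model == "gaussian":
        return I + level * I.max() * rng.standard_normal(I.shape)
    if model == "poisson":
        n_max = 1.0 / level**2
        scale = I.max() / n_max
        return rng.poisson(I / scale).astype(float) * scale
    raise ValueError(f"unknown noise model {model!r}")


def system_magnification(objective_mag: float, relay_focal_lengths_mm) -> float:
    """Total magnification of objective + relay telescope: ``M f4/f3``."""
    f3, f4 = relay_focal_lengths_mm
    if objective_mag <= 0 or f3 <= 0 or f4 <= 0:
        raise ValueError("magnification and focal lengths must be positive")
    return float(objective_mag) * float(f4) / float(f3)
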