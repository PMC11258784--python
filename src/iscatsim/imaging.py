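"""Vectorial imaging through an aplanatic two-lens system (Richards-Wolf).

The objective is modeled by two Gaussian reference spheres of focal lengths
``f`` and ``f'``.  A far field (or a set of plane waves) expanded about the
focus is redirected at the first sphere, optionally transformed in the back
focal plane (BFP) by a per-direction Jones action ``Pi``, and focused by the
second sphere onto the camera.  The TE (phi) component keeps its
orientation, the TM (theta) component is rotated to the image-side radial
direction, and the ray-bundle energy factor ``sqrt(n cos th / n' cos th')``
is applied.  The image side is treated paraxially (``cos th' ~ 1``,
``f' >> f``), and the sine condition maps ``sin th' = (f/f') sin th`` so a
source displacement ``delta`` moves the image by ``M delta``.

Conventions fixed here (asserted by tests, not tunable):

* image coordinates are *object-referred* (image coordinate divided by the
  magnification ``M``), so fields of view read in sample-plane nm;
* the arbitrary global phase of the imaging integral is set to zero and the
  intensity scale is normalized so a unit on-axis reference plane wave maps
  to unit image intensity with ``Pi`` = identity;
* with this normalization the integrated image-plane intensity equals the
  collected-cone integral of ``|F|^2`` over solid angle (energy
  conservation through the train), and the far-field and plane-wave paths
  interfere with the physically correct relative amplitude
  ``eps = i k F / (2 pi)`` fixed by the stationary-phase limit.

The direct integral and the azimuthal-FFT/Bessel-kernel evaluation
(``image_farfield_bessel``) agree in the joint refinement limit; the Bessel
path integrates the azimuthal coordinate analytically per Fourier order and
therefore avoids the large-radius discretization artifacts of the direct
sum at modest azimuthal grid sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import jv

from .fields import FarField, PlaneWaveDecomposition, SphereGrid

__all__ = [
    "OpticalTrain",
    "CameraImage",
    "ImageGrid",
    "magnification",
    "image_farfield",
    "image_farfield_bessel",
    "image_pwd",
    "focus_beam",
    "bfp_waveplate",
    "bfp_attenuator",
    "bfp_block",
    "bfp_compose",
]

#: BFP transform signature: (theta, phi, E2) -> E2', with E2 the transverse
#: Cartesian field components per direction, shape (..., 2).
BFPTransform = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class OpticalTrain:
    """Aplanatic imaging train (object side unprimed, image side primed)."""

    NA: float
    n: float = 1.5
    n_prime: float = 1.0
    f_mm: float = 1.0
    f_prime_mm: float = 100.0
    bfp: BFPTransform | None = None

    def __post_init__(self):
        if self.NA > self.n:
            raise ValueError("NA exceeds object-side index")
        if self.f_mm <= 0 or self.f_prime_mm <= 0:
            raise ValueError("focal lengths must be positive")

    @classmethod
    def from_magnification(
        cls, NA, n=1.5, n_prime=1.0, magnification=100.0, bfp=None
    ) -> "OpticalTrain":
        f = 1.0
        f_prime = magnification * f * n_prime / n
        return cls(NA, n, n_prime, f, f_prime, bfp)

    @property
    def theta_max(self) -> float:
        return float(np.arcsin(self.NA / self.n))

    @property
    def magnification(self) -> float:
        return (self.n / self.n_prime) * (self.f_prime_mm / self.f_mm)


def magnification(train: OpticalTrain) -> float:
    """Aplanatic (sine-condition) transverse magnification (n/n')(f'/f)."""
    return train.magnification


@dataclass(frozen=True)
class ImageGrid:
    """Camera sampling in object-referred coordinates (nm)."""

    x: np.ndarray
    y: np.ndarray

    @classmethod
    def centered(cls, fov_nm: float, n_pixels: int) -> "ImageGrid":
        half = 0.5 * fov_nm
        c = (np.arange(n_pixels) + 0.5) / n_pixels * fov_nm - half
        return cls(x=c, y=c.copy())

    @property
    def XY(self):
        return np.meshgrid(self.x, self.y, indexing="xy")


@dataclass(frozen=True)
class CameraImage:
    """Complex transverse image field and intensity on the camera.

    ``field`` has shape (ny, nx, 2) holding the (x, y) components; the grid
    is object-referred (image coordinates divided by the magnification).
    """

    grid: ImageGrid
    field: np.ndarray

    @property
    def intensity(self) -> np.ndarray:
        return np.sum(np.abs(self.field) ** 2, axis=-1)

    def power(self) -> float:
        """Integrated image intensity (object-referred area element)."""
        dx = self.grid.x[1] - self.grid.x[0]
        dy = self.grid.y[1] - self.grid.y[0]
        return float(self.intensity.sum() * dx * dy)

    def __add__(self, other: "CameraImage") -> "CameraImage":
        return CameraImage(self.grid, self.field + other.field)

    def __sub__(self, other: "CameraImage") -> "CameraImage":
        return CameraImage(self.grid, self.field - other.field)

    def __mul__(self, c) -> "CameraImage":
        return CameraImage(self.grid, self.field * c)

    __rmul__ = __mul__


# ---------------------------------------------------------------------------
# BFP transforms
# ---------------------------------------------------------------------------

def bfp_waveplate(retardance_rad: float, fast_axis_deg: float) -> BFPTransform:
    """Jones wave plate with the fast axis at ``fast_axis_deg`` from x."""
    a = np.deg2rad(fast_axis_deg)
    c, s = np.cos(a), np.sin(a)
    R = np.array([[c, -s], [s, c]])
    J = R @ np.diag([1.0, np.exp(1j * retardance_rad)]) @ R.T

    def pi(theta, phi, E2):
        return E2 @ J.T

    return pi


def bfp_attenuator(t: complex) -> BFPTransform:
    """Uniform amplitude attenuation, ``|t| <= 1``."""
    if abs(t) > 1 + 1e-12:
        raise ValueError("|t| must be <= 1 for a passive attenuator")

    def pi(theta, phi, E2):
        return E2 * t

    return pi


def bfp_block(theta_outer: float, theta_inner: float = 0.0) -> BFPTransform:
    """Annular beam block: zero transmission for theta in [inner, outer]."""

    def pi(theta, phi, E2):
        blocked = (theta >= theta_inner) & (theta <= theta_outer)
        return np.where(blocked[..., None], 0.0, E2)

    return pi


def bfp_compose(*transforms: BFPTransform) -> BFPTransform:
    """Compose Jones actions, applied left to right."""

    def pi(theta, phi, E2):
        for t in transforms:
            E2 = t(theta, phi, E2)
        return E2

    return pi


# ---------------------------------------------------------------------------
# mapping of far-field components into the BFP / image plane
# ---------------------------------------------------------------------------

def _map_to_bfp(train, theta, phi, F_theta, F_phi):
    """TE/TM components -> transverse Cartesian image-side field (.., 2).

    TM (theta) components rotate to the image-side radial direction, TE
    (phi) components keep their orientation; the aplanatic energy factor
    ``sqrt(n cos th/(n' cos th'))`` with the paraxial image side gives the
    ``sqrt(cos th)`` apodization (constant index factors are absorbed by the
    unit-reference normalization).
    """
    cp, sp = np.cos(phi), np.sin(phi)
    E2 = np.stack(
        [F_theta * cp - F_phi * sp, F_theta * sp + F_phi * cp], axis=-1
    )
    E2 = np.sqrt(np.cos(theta))[..., None] * E2
    if train.bfp is not None:
        E2 = train.bfp(theta, phi, E2)
    return E2


def _check_bandwidth(grid: SphereGrid, train, image_grid: ImageGrid, k: float):
    rho_max = float(
        np.sqrt(np.max(np.abs(image_grid.x)) ** 2 + np.max(np.abs(image_grid.y)) ** 2)
    )
    cycles = k * np.sin(train.theta_max) * rho_max / (2 * np.pi)
    n_phi = len(grid.phi)
    if n_phi < 4 * cycles:
        warnings.warn(
            f"azimuthal grid (n_phi={n_phi}) is coarse for the requested field "
            f"of view (~{cycles:.0f} phase cycles); expect large-radius "
            "artifacts in the direct evaluation",
            stacklevel=3,
        )


def _collection_mask(grid: SphereGrid, train) -> np.ndarray:
    return grid.theta <= train.theta_max + 1e-12


def image_farfield(
    far: FarField, train: OpticalTrain, image_grid: ImageGrid
) -> CameraImage:
    """Direct two-dimensional quadrature of the imaging integral.

    The far field must be expanded about the focus with the optical axis
    along +z (rotate/shift beforehand).  Directions beyond ``theta_max``
    are not collected.
    """
    if far.grid is None:
        raise ValueError("imaging needs a structured far-field grid")
    g = far.grid
    _check_bandwidth(g, train, image_grid, far.k)
    sel = _collection_mask(g, train)
    theta = g.theta[sel]
    phi = g.phi
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    F_th, F_ph = far.theta_phi_components()
    E2 = _map_to_bfp(train, TH, PH, F_th[sel], F_ph[sel])     # (nth, nph, 2)
    w = g.weights[sel]
    st = np.sin(theta)
    kx = far.k * st[:, None] * np.cos(phi)[None, :]
    ky = far.k * st[:, None] * np.sin(phi)[None, :]
    x, y = image_grid.x, image_grid.y
    ny, nx = len(y), len(x)
    field = np.zeros((ny, nx, 2), dtype=complex)
    # the plane-wave phase is separable over the rectangular camera grid:
    # exp(i(kx x + ky y)) = exp(i ky y) (outer) exp(i kx x)
    for t in range(len(theta)):            # row-wise to bound memory
        ex = np.exp(1j * kx[t, :, None] * x[None, :])          # (nph, nx)
        ey = np.exp(1j * ky[t, :, None] * y[None, :])          # (nph, ny)
        for c in range(2):
            field[:, :, c] += (ey * (w[t] * E2[t, :, c])[:, None]).T @ ex
    field *= 1j * far.k / (2 * np.pi)
    return CameraImage(image_grid, field)


def image_farfield_bessel(
    far: FarField,
    train: OpticalTrain,
    image_grid: ImageGrid,
    m_max: int | None = None,
) -> CameraImage:
    """Azimuthal-FFT / analytic-Bessel evaluation of the imaging integral.

    The azimuthal far-field dependence is expanded in Fourier orders
    (uniform phi grid required); each order is integrated analytically in
    phi, leaving radial kernels ``J_m(k rho sin th)`` summed over
    ``|m| <= m_max`` (default: no truncation).
    """
    if far.grid is None:
        raise ValueError("imaging needs a structured far-field grid")
    g = far.grid
    n_phi = len(g.phi)
    if m_max is None:
        m_max = n_phi // 2
    if m_max > n_phi // 2:
        raise ValueError("m_max exceeds the azimuthal Nyquist order n_phi/2")
    sel = _collection_mask(g, train)
    theta = g.theta[sel]
    TH, PH = np.meshgrid(theta, g.phi, indexing="ij")
    F_th, F_ph = far.theta_phi_components()
    E2 = _map_to_bfp(train, TH, PH, F_th[sel], F_ph[sel])     # (nth, nph, 2)
    gm = np.fft.fft(E2, axis=1) / n_phi                        # orders 0..n-1
    freqs = np.fft.fftfreq(n_phi, d=1.0 / n_phi).astype(int)   # signed m
    X, Y = image_grid.XY
    rho = np.hypot(X, Y)
    phi_im = np.arctan2(Y, X)
    st = np.sin(theta)
    w = g.w_cos[sel]
    field = np.zeros(X.shape + (2,), dtype=complex)
    arg = far.k * st[:, None, None] * rho[None, :, :]
    arg_max = float(arg.max())
    xtab = np.linspace(0.0, arg_max * (1 + 1e-9) + 1e-9, 60001)
    g_scale = float(np.abs(gm).max()) + 1e-300
    for idx, m in enumerate(freqs):
        if abs(m) > m_max:
            continue
        if np.abs(gm[:, idx, :]).max() < 1e-14 * g_scale:
            continue                       # azimuthal order not present
        Jm = np.interp(arg, xtab, jv(m, xtab))                 # (nth, ny, nx)
        radial = np.einsum("t,tc,tyx->yxc", w, gm[:, idx, :], Jm)
        field += (1j**m) * np.exp(1j * m * phi_im)[..., None] * radial
    field *= 1j * far.k
    return CameraImage(image_grid, field)


def image_pwd(
    pwd: PlaneWaveDecomposition, train: OpticalTrain, image_grid: ImageGrid
) -> CameraImage:
    """Image a (reference/reflected) beam given as discrete plane waves.

    Each plane wave maps to an image-plane plane wave with transverse
    frequency set by the sine condition; a unit on-axis wave maps to unit
    image intensity (normalization convention).  Components beyond
    ``theta_max`` are dropped with a warning.
    """
    d = pwd.directions
    ct = np.clip(d[:, 2], -1.0, 1.0)
    theta = np.arccos(ct)
    keep = theta <= train.theta_max + 1e-12
    if not np.all(keep):
        warnings.warn(
            f"{np.sum(~keep)} plane-wave components beyond the collection "
            "cone were dropped",
            stacklevel=2,
        )
    X, Y = image_grid.XY
    field = np.zeros(X.shape + (2,), dtype=complex)
    th_hat_f = lambda th, ph: np.array(
        [np.cos(th) * np.cos(ph), np.cos(th) * np.sin(ph), -np.sin(th)]
    )
    for j in np.nonzero(keep)[0]:
        th = theta[j]
        ph = float(np.arctan2(d[j, 1], d[j, 0])) if th > 1e-12 else 0.0
        eps = pwd.amplitudes[j]
        a_th = eps @ th_hat_f(th, ph)
        a_ph = eps @ np.array([-np.sin(ph), np.cos(ph), 0.0])
        E2 = _map_to_bfp(train, np.array(th), np.array(ph), a_th, a_ph)
        ramp = np.exp(
            1j * pwd.k * np.sin(th) * (np.cos(ph) * X + np.sin(ph) * Y)
        )
        field += ramp[..., None] * E2
    return CameraImage(image_grid, field)


def focus_beam(
    aperture_field: Callable[[np.ndarray, np.ndarray], np.ndarray],
    train: OpticalTrain,
    wavelength_nm: float,
    n_theta: int = 40,
    n_phi: int = 41,
) -> PlaneWaveDecomposition:
    """Vectorial focal field of a focused beam as a plane-wave superposition.

    ``aperture_field(rho_norm, phi)`` returns the transverse (x, y) Jones
    components of the collimated input on the BFP, with ``rho_norm =
    sin th / sin th_max`` in [0, 1].  The returned decomposition evaluates
    the focal field in the object medium; its amplitudes carry the
    angular-spectrum quadrature weights.
    """
    grid = SphereGrid.cap(train.theta_max, n_theta, n_phi, pole="up")
    th = grid.theta
    TH, PH = np.meshgrid(th, grid.phi, indexing="ij")
    rho_norm = np.sin(TH) / np.sin(train.theta_max)
    E_ap = np.asarray(aperture_field(rho_norm, PH), dtype=complex)
    if E_ap.shape != TH.shape + (2,):
        raise ValueError("aperture_field must return shape (..., 2)")
    # focusing: radial -> theta-hat, azimuthal -> phi-hat, sqrt(cos) apodization
    cp, sp = np.cos(PH), np.sin(PH)
    a_r = E_ap[..., 0] * cp + E_ap[..., 1] * sp
    a_p = -E_ap[..., 0] * sp + E_ap[..., 1] * cp
    apod = np.sqrt(np.cos(TH))
    th_hat = np.stack([np.cos(TH) * cp, np.cos(TH) * sp, -np.sin(TH)], axis=-1)
    ph_hat = np.stack([-sp, cp, np.zeros_like(sp)], axis=-1)
    eps = apod[..., None] * (a_r[..., None] * th_hat + a_p[..., None] * ph_hat)
    k = 2 * np.pi * train.n / wavelength_nm
    amps = (1j * k / (2 * np.pi)) * grid.weights[..., None] * eps
    return PlaneWaveDecomposition(
        directions=grid.directions.reshape(-1, 3),
        amplitudes=amps.reshape(-1, 3),
        k=k,
        n_medium=train.n,
        weights=grid.weights.reshape(-1),
    )
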