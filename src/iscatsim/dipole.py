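"""Point-dipole scattering models.

A small particle is modeled as a polarizable point: the quasistatic
Clausius-Mossotti polarizability turns the local driving field into an
induced dipole moment, whose emission is propagated to the far field either

* ``dip1`` — the exact asymptotic far field of a dipole above a single
  interface (direct + Fresnel-weighted image ray above, Snell-mapped
  Fresnel-transmitted ray below, including the evanescent continuation into
  supercritical angles), or
* ``dip2`` — dipole radiation in homogeneous space followed by the ray-wise
  interface correction of :mod:`iscatsim.interface` (works for arbitrary
  layer stacks).

For a single interface the two constructions coincide; they are kept as
independent code paths and cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

from .fields import FarField, SphereGrid
from .interface import DipoleFarFieldSource, interface_correct
from .layers import LayerStack, stack_rt

__all__ = [
    "polarizability_sphere",
    "DipoleScatterer",
    "dipole_farfield_dip1",
    "dipole_farfield_dip2",
]


def polarizability_sphere(
    diameter_nm: float,
    eps_particle: complex,
    eps_host: complex,
    radiative_correction: bool = False,
    wavelength_nm: float | None = None,
) -> complex:
    """Quasistatic sphere polarizability ``4 pi a^3 (ep - eh)/(ep + 2 eh)``.

    Units: nm^3, normalized so the induced far field is
    ``F = k^2 alpha E / (4 pi)`` with ``k`` the host wavenumber.  The
    radiative (radiation-reaction) correction is off by default; switching
    it on requires the wavelength.
    """
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    ep, eh = complex(eps_particle), complex(eps_host)
    den = ep + 2 * eh
    if abs(den) < 1e-12:
        raise ValueError("quasistatic resonance (eps_p + 2 eps_h = 0)")
    a = 0.5 * diameter_nm
    alpha = 4 * np.pi * a**3 * (ep - eh) / den
    if radiative_correction:
        if wavelength_nm is None:
            raise ValueError("radiative correction needs wavelength_nm")
        k = 2 * np.pi * np.sqrt(eh).real / wavelength_nm
        alpha = alpha / (1 - 1j * k**3 * alpha / (6 * np.pi))
    return complex(alpha)


class DipoleScatterer:
    """A polarizable point particle.

    ``polarizability`` is a complex scalar (isotropic) or a 3x3 tensor in
    nm^3; ``position`` is the dipole location in sample coordinates (nm,
    interface at z = 0); ``n_host`` the refractive index of the embedding
    (upper) medium.
    """

    def __init__(self, position, polarizability, n_host: float, wavelength_nm: float):
        self.position = np.asarray(position, dtype=float)
        alpha = np.asarray(polarizability, dtype=complex)
        if alpha.ndim == 0:
            alpha = alpha * np.eye(3)
        if alpha.shape != (3, 3):
            raise ValueError("polarizability must be scalar or 3x3")
        self.alpha = alpha
        self.n_host = float(n_host)
        self.wavelength = float(wavelength_nm)
        self.k = 2 * np.pi * self.n_host / self.wavelength

    def induced_moment(self, drive) -> np.ndarray:
        """p = alpha . E_drive(position); drive is a field evaluator."""
        E = _drive_field(drive, self.position)
        return self.alpha @ E

    def free_source(self, drive) -> DipoleFarFieldSource:
        return DipoleFarFieldSource(self.induced_moment(drive), self.k, self.n_host)


def _drive_field(drive, position) -> np.ndarray:
    pts = np.asarray(position, dtype=float)[None, :]
    if hasattr(drive, "electric"):
        return np.asarray(drive.electric(pts))[0]
    return np.asarray(drive(pts))[0]


def _check_above(dip: DipoleScatterer):
    if dip.position[2] <= 0:
        raise ValueError("dipole must sit strictly above the top interface")


def dipole_farfield_dip1(
    dip: DipoleScatterer,
    drive,
    stack: LayerStack,
    side: str = "below",
    grid: SphereGrid | None = None,
) -> FarField:
    """Exact far field of a point dipole above a *single* interface.

    The output is expanded about the interface origin; the dipole's lateral
    position enters as a linear phase.
    """
    _check_above(dip)
    if len(stack.materials) != 2:
        raise ValueError("dip1 handles a single interface only; use dip2")
    p = dip.induced_moment(drive)
    k1 = dip.k
    n1 = dip.n_host
    lam = dip.wavelength
    n2 = stack.bottom.refractive_index(lam).real
    h = dip.position[2]
    if grid is None:
        grid = SphereGrid.cap(np.pi / 2, pole="up" if side == "above" else "down")
    d = grid.directions
    phi = np.arctan2(d[..., 1], d[..., 0])
    s_hat = np.zeros(d.shape)
    s_hat[..., 0] = -np.sin(phi)
    s_hat[..., 1] = np.cos(phi)

    def free_amp(dirs):
        dirs = np.asarray(dirs, dtype=complex)
        return (k1**2 / (4 * np.pi)) * (p - dirs * (dirs @ p)[..., None])

    if side == "above":
        dz = d[..., 2]
        r_te = stack_rt(stack, dz.ravel(), "TE", lam, "down")[0].reshape(dz.shape)
        r_tm = stack_rt(stack, dz.ravel(), "TM", lam, "down")[0].reshape(dz.shape)
        dm = d.copy()
        dm[..., 2] = -dz
        Fm = free_amp(dm)
        Fs = np.sum(Fm * s_hat, axis=-1)
        Fp = np.sum(Fm * np.cross(s_hat, dm), axis=-1)
        p_up = np.cross(s_hat, d)
        F = (
            np.exp(-1j * k1 * h * dz)[..., None] * free_amp(d)
            + np.exp(1j * k1 * h * dz)[..., None]
            * ((r_te * Fs)[..., None] * s_hat - (r_tm * Fp)[..., None] * p_up)
        )
        out = FarField.on_grid(grid, F, k1, n1)
    elif side == "below":
        cos2 = -d[..., 2]
        if np.any(cos2 < -1e-12):
            raise ValueError("below-side grid must point downward")
        sin2 = np.sqrt(np.clip(1 - cos2**2, 0, None))
        sin1 = (n2 / n1) * sin2
        cos1 = np.sqrt(1 - sin1.astype(complex) ** 2)
        cos1 = np.where(cos1.imag < 0, -cos1, cos1)
        d1 = np.empty(d.shape, dtype=complex)
        d1[..., 0] = sin1 * np.cos(phi)
        d1[..., 1] = sin1 * np.sin(phi)
        d1[..., 2] = -cos1
        F1 = free_amp(d1)
        Fs = np.sum(F1 * s_hat, axis=-1)
        Fp = np.sum(F1 * np.cross(s_hat.astype(complex), d1), axis=-1)
        t_te = stack_rt(stack, cos1.ravel(), "TE", lam, "down")[1].reshape(cos1.shape)
        t_tm = stack_rt(stack, cos1.ravel(), "TM", lam, "down")[1].reshape(cos1.shape)
        amp = (n2 * cos2) / (n1 * cos1) * np.exp(1j * k1 * cos1 * h)
        p2 = np.cross(s_hat, d)
        F = (t_te * Fs * amp)[..., None] * s_hat + (t_tm * Fp * amp)[..., None] * p2
        out = FarField.on_grid(grid, F, k1 * n2 / n1, n2)
    else:
        raise ValueError("side must be 'above' or 'below'")
    # lateral position enters as a linear phase about the interface origin
    lateral = np.array([dip.position[0], dip.position[1], 0.0])
    return out.shift(lateral) if np.any(lateral) else out


def dipole_farfield_dip2(
    dip: DipoleScatterer,
    drive,
    stack: LayerStack,
    side: str = "below",
    grid: SphereGrid | None = None,
) -> FarField:
    """Homogeneous dipole radiation + ray-wise stack correction (any stack)."""
    _check_above(dip)
    src = dip.free_source(drive)
    out = interface_correct(src, stack, dip.position[2], side=side, grid=grid)
    lateral = np.array([dip.position[0], dip.position[1], 0.0])
    return out.shift(lateral) if np.any(lateral) else out
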