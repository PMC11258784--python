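"""Mie theory for homogeneous spheres.

Exact-sphere reference solution used both as a scattering engine for
spherical particles and as the oracle against which the boundary-element
solver is validated.  Conventions follow the standard treatment (incident
``x``-polarized plane wave along ``+z``; ``e^{-i omega t}``), generalized to
arbitrary incidence direction and complex polarization by rotation and
superposition.

The angular amplitude functions accept complex observation directions
(``d . d = 1`` with complex components), which provides the analytic
continuation needed to propagate evanescent components through a substrate
interface (supercritical-angle emission).
"""

from __future__ import annotations

import numpy as np
from scipy.special import spherical_jn, spherical_yn

from .fields import FarField, SphereGrid
from .layers import PlaneWaveSpec, polarization_basis

__all__ = ["MieSphere", "mie_farfield", "mie_cross_sections"]


def _n_max(x: float) -> int:
    """Standard series-truncation rule for size parameter x."""
    return int(np.ceil(x + 4.05 * x ** (1 / 3) + 2)) + 2


def _riccati_psi(n_arr, z):
    """psi_n(z) = z j_n(z) and derivative, complex-capable."""
    jn = np.array([spherical_jn(int(n), z) for n in n_arr])
    jnp = np.array([spherical_jn(int(n), z, derivative=True) for n in n_arr])
    return z * jn, jn + z * jnp


def _riccati_xi(n_arr, z):
    """xi_n(z) = z h1_n(z) and derivative (outgoing for e^{-i omega t})."""
    jn = np.array([spherical_jn(int(n), z) for n in n_arr])
    yn = np.array([spherical_yn(int(n), z) for n in n_arr])
    jnp = np.array([spherical_jn(int(n), z, derivative=True) for n in n_arr])
    ynp = np.array([spherical_yn(int(n), z, derivative=True) for n in n_arr])
    hn = jn + 1j * yn
    hnp = jnp + 1j * ynp
    return z * hn, hn + z * hnp


def _pi_tau(n_max: int, mu):
    """Angular functions pi_n, tau_n for (complex) mu = cos(Theta)."""
    mu = np.asarray(mu, dtype=complex)
    pi = np.zeros((n_max + 1,) + mu.shape, dtype=complex)
    tau = np.zeros_like(pi)
    pi[1] = 1.0
    tau[1] = mu
    for n in range(2, n_max + 1):
        pi[n] = ((2 * n - 1) * mu * pi[n - 1] - n * pi[n - 2]) / (n - 1)
        tau[n] = n * mu * pi[n] - (n + 1) * pi[n - 1]
    return pi[1:], tau[1:]


class MieSphere:
    """Mie solution for a homogeneous sphere in a homogeneous host.

    Parameters
    ----------
    diameter_nm:
        Sphere diameter (nm), > 0.
    eps_particle, eps_host:
        Relative permittivities at the working wavelength (host must be
        lossless for cross sections to be meaningful).
    wavelength_nm:
        Vacuum wavelength (nm).
    """

    def __init__(self, diameter_nm, eps_particle, eps_host, wavelength_nm):
        if diameter_nm <= 0:
            raise ValueError("diameter must be positive")
        self.a = 0.5 * diameter_nm
        self.eps_p = complex(eps_particle)
        self.eps_h = complex(eps_host)
        self.wavelength = float(wavelength_nm)
        self.n_host = np.sqrt(self.eps_h)
        self.k = 2 * np.pi * self.n_host.real / self.wavelength
        self.x = self.k * self.a
        self.m = np.sqrt(self.eps_p) / self.n_host
        self.N = _n_max(self.x)
        self._coefficients()

    def _coefficients(self):
        n_arr = np.arange(1, self.N + 1)
        x, m = self.x, self.m
        psi_x, dpsi_x = _riccati_psi(n_arr, x + 0j)
        psi_mx, dpsi_mx = _riccati_psi(n_arr, m * x)
        xi_x, dxi_x = _riccati_xi(n_arr, x + 0j)
        self.an = (m * psi_mx * dpsi_x - psi_x * dpsi_mx) / (
            m * psi_mx * dxi_x - xi_x * dpsi_mx
        )
        self.bn = (psi_mx * dpsi_x - m * psi_x * dpsi_mx) / (
            psi_mx * dxi_x - m * xi_x * dpsi_mx
        )
        tail = max(abs(self.an[-1]), abs(self.bn[-1]))
        head = max(abs(self.an).max(), abs(self.bn).max())
        if head > 0 and tail / head > 1e-10:
            raise RuntimeError("Mie series not converged at truncation order")

    # -- scalar summaries --------------------------------------------------
    def cross_sections(self) -> tuple[float, float]:
        """(sigma_sca, sigma_ext) in nm^2, defined in the host medium."""
        n = np.arange(1, self.N + 1)
        pref = 2 * np.pi / self.k**2
        sca = pref * np.sum((2 * n + 1) * (np.abs(self.an) ** 2 + np.abs(self.bn) ** 2))
        ext = pref * np.sum((2 * n + 1) * np.real(self.an + self.bn))
        return float(sca), float(ext)

    # -- angular amplitudes ------------------------------------------------
    def S1S2(self, mu):
        """Amplitude functions of the scattering angle, complex-capable."""
        n = np.arange(1, self.N + 1)
        pi_n, tau_n = _pi_tau(self.N, mu)
        w = ((2 * n + 1) / (n * (n + 1)))[:, None]
        a = self.an[:, None]
        b = self.bn[:, None]
        mu = np.atleast_1d(mu)
        S1 = np.sum(w * (a * pi_n.reshape(self.N, -1) + b * tau_n.reshape(self.N, -1)), axis=0)
        S2 = np.sum(w * (a * tau_n.reshape(self.N, -1) + b * pi_n.reshape(self.N, -1)), axis=0)
        return S1.reshape(np.shape(mu)), S2.reshape(np.shape(mu))

    def farfield_amplitude(self, directions, k_hat, polarization, amplitude=1.0):
        """Far-field amplitude F(d) for a plane-wave drive.

        ``directions`` may be complex with ``d . d = 1`` (analytic
        continuation); ``k_hat`` is the (real) incidence direction and
        ``polarization`` the transverse (possibly complex) drive amplitude
        vector.
        """
        d = np.asarray(directions, dtype=complex)
        shape = d.shape[:-1]
        d = d.reshape(-1, 3)
        k_hat = np.asarray(k_hat, dtype=float)
        eps0 = np.asarray(polarization, dtype=complex) * amplitude
        mu = d @ k_hat  # cos(Theta), complex-capable
        S1, S2 = self.S1S2(mu)
        # scattering-plane basis, bilinear-normalized for complex directions
        perp = np.cross(np.broadcast_to(k_hat, d.shape), d)
        nrm2 = np.sum(perp * perp, axis=-1)
        F = np.zeros((len(d), 3), dtype=complex)
        reg = np.abs(nrm2) > 1e-16
        if np.any(reg):
            e_perp = perp[reg] / np.sqrt(nrm2[reg])[:, None]
            e_par_in = np.cross(e_perp, k_hat)
            e_par_out = np.cross(e_perp, d[reg])
            a_par = e_par_in @ eps0
            a_perp = e_perp @ eps0
            F[reg] = (1j / self.k) * (
                S2[reg][:, None] * a_par[:, None] * e_par_out
                + S1[reg][:, None] * a_perp[:, None] * e_perp
            )
        if np.any(~reg):
            # forward/backward direction: S1 = S2, isotropic transverse action
            proj = eps0 - d[~reg] * (d[~reg] @ eps0)[:, None]
            F[~reg] = (1j / self.k) * S1[~reg][:, None] * proj
        return F.reshape(shape + (3,))

    # -- scattered near field ----------------------------------------------
    def nearfield_scattered(self, points, k_hat, polarization, amplitude=1.0):
        """Scattered E outside the sphere (vector spherical harmonic sum)."""
        k_hat = np.asarray(k_hat, dtype=float)
        eps0 = np.asarray(polarization, dtype=complex) * amplitude
        # build an orthonormal frame with z' = k_hat; decompose polarization
        # into two linear drives along x' and y' and superpose
        tmp = np.array([1.0, 0.0, 0.0])
        if abs(k_hat @ tmp) > 0.9:
            tmp = np.array([0.0, 1.0, 0.0])
        x1 = tmp - k_hat * (tmp @ k_hat)
        x1 /= np.linalg.norm(x1)
        y1 = np.cross(k_hat, x1)
        cx, cy = eps0 @ x1, eps0 @ y1
        out = np.zeros((np.atleast_2d(points).shape[0], 3), dtype=complex)
        for c, xdir, ydir in ((cx, x1, y1), (cy, y1, -x1)):
            if abs(c) == 0:
                continue
            R = np.stack([xdir, ydir, k_hat])  # rows: lab frame of x',y',z'
            pts_loc = np.atleast_2d(points) @ R.T
            E_loc = self._nearfield_xpol(pts_loc)
            out += c * (E_loc @ R)
        return out

    def _nearfield_xpol(self, points):
        """Canonical frame: x-polarized unit plane wave along +z."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(pts, axis=1)
        if np.any(r < self.a):
            raise ValueError("near-field points must lie outside the sphere")
        theta = np.arccos(np.clip(pts[:, 2] / r, -1, 1))
        phi = np.arctan2(pts[:, 1], pts[:, 0])
        rho = self.k * r
        mu = np.cos(theta)
        n_arr = np.arange(1, self.N + 1)
        pi_n, tau_n = _pi_tau(self.N, mu + 0j)
        jn = np.array([spherical_jn(int(n), rho) for n in n_arr])
        yn = np.array([spherical_yn(int(n), rho) for n in n_arr])
        jnp = np.array([spherical_jn(int(n), rho, derivative=True) for n in n_arr])
        ynp = np.array([spherical_yn(int(n), rho, derivative=True) for n in n_arr])
        hn = jn + 1j * yn
        dzh = hn / rho + (jnp + 1j * ynp)   # [rho h]'/rho
        En = (1j ** n_arr * (2 * n_arr + 1) / (n_arr * (n_arr + 1)))[:, None]
        a = self.an[:, None]
        b = self.bn[:, None]
        sin_t = np.sin(theta)
        # E = sum En (i a N_e1n - b M_o1n), components (r, theta, phi)
        Er = np.sum(1j * En * a * (n_arr * (n_arr + 1))[:, None] * sin_t * pi_n * hn / rho, axis=0) * np.cos(phi)
        Et = np.cos(phi) * np.sum(En * (1j * a * tau_n * dzh - b * pi_n * hn), axis=0)
        Ep = -np.sin(phi) * np.sum(En * (1j * a * pi_n * dzh - b * tau_n * hn), axis=0)
        # spherical -> Cartesian
        st, ct = np.sin(theta), np.cos(theta)
        cp, sp = np.cos(phi), np.sin(phi)
        E = np.empty((len(pts), 3), dtype=complex)
        E[:, 0] = Er * st * cp + Et * ct * cp - Ep * sp
        E[:, 1] = Er * st * sp + Et * ct * sp + Ep * cp
        E[:, 2] = Er * ct - Et * st
        return E


def mie_farfield(
    diameter_nm: float,
    eps_particle: complex,
    eps_host: complex,
    drive: PlaneWaveSpec,
    grid: SphereGrid | None = None,
) -> FarField:
    """Far field of a sphere under a single plane-wave drive.

    The drive lives in the homogeneous host; its wavelength sets the series.
    """
    sph = MieSphere(diameter_nm, eps_particle, eps_host, drive.wavelength_nm)
    if grid is None:
        grid = SphereGrid.full_sphere()
    k_hat = drive.k_hat()
    a_s, a_p = drive.jones() * drive.amplitude
    s_hat, p_hat = polarization_basis(drive.azimuth_deg, k_hat)
    eps0 = a_s * s_hat + a_p * p_hat
    F = sph.farfield_amplitude(grid.directions, k_hat, eps0)
    return FarField.on_grid(grid, F, sph.k, float(sph.n_host.real))


def mie_cross_sections(diameter_nm, eps_particle, eps_host, wavelength_nm):
    """(sigma_sca, sigma_ext) in nm^2 for a sphere in a lossless host."""
    return MieSphere(diameter_nm, eps_particle, eps_host, wavelength_nm).cross_sections()
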