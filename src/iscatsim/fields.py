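"""Far fields and plane-wave decompositions, with their rigid transforms.

Two field representations travel through the pipeline:

* :class:`FarField` — outgoing spherical waves ``E(r) = F(rhat) e^{ikr}/r``
  sampled on a direction grid; the currency between scattering solvers and
  the imaging stage.
* :class:`PlaneWaveDecomposition` — a discrete superposition
  ``E(r) = sum_j eps_j e^{i k khat_j . r}``; represents incoming/reference
  beams (a collimated beam is a single term).

Direction grids use Gauss-Legendre nodes in ``cos(theta)`` crossed with a
uniform (periodic trapezoid) azimuthal grid, so angular quadrature is
spectrally accurate for smooth patterns.  Vector amplitudes are stored in
Cartesian components, which makes rotations exact; TE/TM (theta/phi)
projections are computed on demand for imaging.

Under the package's ``e^{-i omega t}`` convention, shifting the expansion
origin by ``r0`` multiplies each direction by ``e^{-i k khat . r0}``; the
sign is pinned by the asymptotic re-expansion test rather than convention
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .layers import PlaneWaveSpec, polarization_basis

__all__ = [
    "SphereGrid",
    "FarField",
    "PlaneWaveDecomposition",
    "make_planewave",
    "rotation_about_axis",
    "ROT_X_180",
]


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------

def rotation_about_axis(axis, angle_rad: float) -> np.ndarray:
    """Proper rotation matrix about an arbitrary axis (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


#: Detection-axis rotation used for iSCAT: maps -z (collection) onto +z.
ROT_X_180 = rotation_about_axis([1.0, 0.0, 0.0], np.pi)


def _check_rotation(R: np.ndarray):
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-12):
        raise ValueError("R must be orthogonal to 1e-12")
    if np.linalg.det(R) < 0:
        raise ValueError("improper rotation (det = -1) rejected")
    return R


# ---------------------------------------------------------------------------
# direction grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereGrid:
    """Structured (theta, phi) direction grid with quadrature weights."""

    theta: np.ndarray   # (n_theta,) polar angles, rad, increasing
    phi: np.ndarray     # (n_phi,) azimuths, rad, uniform on [0, 2pi)
    w_cos: np.ndarray   # (n_theta,) Gauss-Legendre weights in cos(theta)

    @classmethod
    def from_theta_range(
        cls, theta_lo: float, theta_hi: float, n_theta: int = 50, n_phi: int = 51
    ) -> "SphereGrid":
        """Gauss-Legendre in cos(theta) on [theta_lo, theta_hi] x uniform phi."""
        if not (0 <= theta_lo < theta_hi <= np.pi):
            raise ValueError("need 0 <= theta_lo < theta_hi <= pi")
        x, w = np.polynomial.legendre.leggauss(n_theta)
        c_lo, c_hi = np.cos(theta_hi), np.cos(theta_lo)
        c = 0.5 * (c_hi - c_lo) * x + 0.5 * (c_hi + c_lo)
        w = 0.5 * (c_hi - c_lo) * w
        order = np.argsort(-c)  # increasing theta
        theta = np.arccos(c[order])
        phi = 2 * np.pi * np.arange(n_phi) / n_phi
        return cls(theta=theta, phi=phi, w_cos=w[order])

    @classmethod
    def full_sphere(cls, n_theta: int = 50, n_phi: int = 51) -> "SphereGrid":
        return cls.from_theta_range(0.0, np.pi, n_theta, n_phi)

    @classmethod
    def cap(
        cls,
        theta_max: float,
        n_theta: int = 50,
        n_phi: int = 51,
        pole: str = "up",
    ) -> "SphereGrid":
        """Polar cap of half-angle ``theta_max`` about +z (``pole='up'``) or -z."""
        if pole == "up":
            return cls.from_theta_range(0.0, theta_max, n_theta, n_phi)
        return cls.from_theta_range(np.pi - theta_max, np.pi, n_theta, n_phi)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.theta), len(self.phi)

    @property
    def directions(self) -> np.ndarray:
        """Unit vectors, shape (n_theta, n_phi, 3)."""
        st, ct = np.sin(self.theta), np.cos(self.theta)
        cp, sp = np.cos(self.phi), np.sin(self.phi)
        d = np.empty((len(self.theta), len(self.phi), 3))
        d[..., 0] = st[:, None] * cp[None, :]
        d[..., 1] = st[:, None] * sp[None, :]
        d[..., 2] = ct[:, None] * np.ones_like(cp)[None, :]
        return d

    @property
    def weights(self) -> np.ndarray:
        """Solid-angle quadrature weights, shape (n_theta, n_phi)."""
        return np.broadcast_to(
            self.w_cos[:, None] * (2 * np.pi / len(self.phi)),
            (len(self.theta), len(self.phi)),
        ).copy()

    @property
    def solid_angle(self) -> float:
        return float(self.weights.sum())

    def unit_vectors(self):
        """theta-hat and phi-hat fields, each (n_theta, n_phi, 3)."""
        st, ct = np.sin(self.theta), np.cos(self.theta)
        cp, sp = np.cos(self.phi), np.sin(self.phi)
        th = np.empty((len(self.theta), len(self.phi), 3))
        th[..., 0] = ct[:, None] * cp[None, :]
        th[..., 1] = ct[:, None] * sp[None, :]
        th[..., 2] = -st[:, None] * np.ones_like(cp)
        ph = np.zeros_like(th)
        ph[..., 0] = -sp[None, :]
        ph[..., 1] = cp[None, :]
        return th, ph


# ---------------------------------------------------------------------------
# far fields
# ---------------------------------------------------------------------------

def _transversality_defect(directions, amplitudes):
    num = np.abs(np.sum(directions * amplitudes, axis=-1))
    den = np.linalg.norm(amplitudes, axis=-1) + 1e-300
    return float(np.max(num / den))


@dataclass(frozen=True)
class FarField:
    """Outgoing-wave far-field amplitude F(rhat) on a direction set.

    ``amplitudes`` are Cartesian complex vectors; ``k`` is the wavenumber in
    the embedding medium (nm^-1) and ``n_medium`` its refractive index.  A
    structured :class:`SphereGrid` is kept when available (required for
    interpolation/imaging); general rotations fall back to an explicit
    direction list.
    """

    directions: np.ndarray          # (..., 3) unit vectors
    amplitudes: np.ndarray          # (..., 3) complex
    weights: np.ndarray             # (...,) solid-angle weights
    k: float
    n_medium: float = 1.0
    grid: SphereGrid | None = None

    @classmethod
    def on_grid(cls, grid: SphereGrid, amplitudes, k: float, n_medium: float = 1.0):
        amps = np.asarray(amplitudes, dtype=complex)
        if amps.shape != grid.shape + (3,):
            raise ValueError(f"amplitudes must have shape {grid.shape + (3,)}")
        return cls(grid.directions, amps, grid.weights, float(k), float(n_medium), grid)

    def transversality_defect(self) -> float:
        return _transversality_defect(self.directions, self.amplitudes)

    def power(self) -> float:
        """Radiated power, in units of (n/2) |F|^2 integrated over solid angle."""
        return float(
            0.5 * self.n_medium
            * np.sum(self.weights * np.sum(np.abs(self.amplitudes) ** 2, axis=-1))
        )

    def rotate(self, R) -> "FarField":
        """Rotate pattern and polarization: F'(R rhat) = R F(rhat)."""
        R = _check_rotation(R)
        return replace(
            self,
            directions=self.directions @ R.T,
            amplitudes=self.amplitudes @ R.T,
            grid=None if not np.allclose(R, np.eye(3)) else self.grid,
        )

    def shift(self, r0) -> "FarField":
        """Re-expand about an origin shifted by ``r0`` (nm)."""
        r0 = np.asarray(r0, dtype=float)
        phase = np.exp(-1j * self.k * (self.directions @ r0))
        return replace(self, amplitudes=self.amplitudes * phase[..., None])

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Field ``F(rhat) e^{ikr}/r`` at points (N, 3) away from the origin.

        Physically valid for ``r >> lambda`` (not enforced).  Direction
        lookup is bilinear on the structured grid with periodic phi wrap.
        """
        if self.grid is None:
            raise ValueError("evaluate() needs a structured grid (not rotated)")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(pts, axis=1)
        if np.any(r == 0):
            raise ValueError("cannot evaluate the far field at the origin")
        rhat = pts / r[:, None]
        F = self.interp_directions(rhat)
        return F * (np.exp(1j * self.k * r) / r)[:, None]

    def interp_directions(self, rhat: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of F onto arbitrary unit vectors (N, 3)."""
        g = self.grid
        th = np.arccos(np.clip(rhat[:, 2], -1.0, 1.0))
        ph = np.mod(np.arctan2(rhat[:, 1], rhat[:, 0]), 2 * np.pi)
        it = np.clip(np.searchsorted(g.theta, th) - 1, 0, len(g.theta) - 2)
        tt = (th - g.theta[it]) / (g.theta[it + 1] - g.theta[it])
        tt = np.clip(tt, 0.0, 1.0)
        dphi = 2 * np.pi / len(g.phi)
        fp = ph / dphi
        ip = np.floor(fp).astype(int) % len(g.phi)
        tp = fp - np.floor(fp)
        ip1 = (ip + 1) % len(g.phi)
        A = self.amplitudes
        F = (
            (1 - tt)[:, None] * ((1 - tp)[:, None] * A[it, ip] + tp[:, None] * A[it, ip1])
            + tt[:, None] * ((1 - tp)[:, None] * A[it + 1, ip] + tp[:, None] * A[it + 1, ip1])
        )
        return F

    def theta_phi_components(self):
        """(F_theta, F_phi) projections on the structured grid."""
        if self.grid is None:
            raise ValueError("needs a structured grid")
        th, ph = self.grid.unit_vectors()
        return (
            np.sum(self.amplitudes * th, axis=-1),
            np.sum(self.amplitudes * ph, axis=-1),
        )

    def __add__(self, other: "FarField") -> "FarField":
        if not np.allclose(self.directions, other.directions) or self.k != other.k:
            raise ValueError("far fields must share direction grid and wavenumber")
        return replace(self, amplitudes=self.amplitudes + other.amplitudes)

    def __mul__(self, c: complex) -> "FarField":
        return replace(self, amplitudes=self.amplitudes * c)

    __rmul__ = __mul__


# ---------------------------------------------------------------------------
# plane-wave decompositions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaneWaveDecomposition:
    """Discrete plane-wave superposition ``E(r) = sum_j eps_j e^{i k khat_j.r}``.

    For quadrature-type decompositions (focused beams) the quadrature weight
    is already folded into each amplitude; ``weights`` then records the
    solid-angle weights for diagnostics.
    """

    directions: np.ndarray              # (N, 3) unit vectors
    amplitudes: np.ndarray              # (N, 3) complex
    k: float
    n_medium: float = 1.0
    weights: np.ndarray | None = None   # (N,) optional solid-angle weights

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        a = np.atleast_2d(np.asarray(self.amplitudes, dtype=complex))
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "amplitudes", a)
        if d.shape != a.shape:
            raise ValueError("directions and amplitudes must have matching shape")
        defect = _transversality_defect(d, a)
        if defect > 1e-9:
            raise ValueError(f"amplitudes not transverse (defect {defect:.2e})")

    def transversality_defect(self) -> float:
        return _transversality_defect(self.directions, self.amplitudes)

    def rotate(self, R) -> "PlaneWaveDecomposition":
        R = _check_rotation(R)
        return replace(
            self, directions=self.directions @ R.T, amplitudes=self.amplitudes @ R.T
        )

    def shift(self, r0) -> "PlaneWaveDecomposition":
        """Move the phase-reference origin by ``r0`` (nm)."""
        r0 = np.asarray(r0, dtype=float)
        phase = np.exp(-1j * self.k * (self.directions @ r0))
        return replace(self, amplitudes=self.amplitudes * phase[:, None])

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Total field at points (N, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        phases = np.exp(1j * self.k * pts @ self.directions.T)   # (Np, Nw)
        return phases @ self.amplitudes

    def electric(self, points: np.ndarray) -> np.ndarray:
        return self.evaluate(points)

    def fields(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(E, Z0 H) at points; usable as a scattering-solver drive."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        phases = np.exp(1j * self.k * pts @ self.directions.T)
        H_amp = self.n_medium * np.cross(self.directions, self.amplitudes)
        return phases @ self.amplitudes, phases @ H_amp

    def power_flux(self) -> float:
        """Summed plane-wave intensity (n/2) sum |eps_j|^2 (diagnostic)."""
        return float(
            0.5 * self.n_medium * np.sum(np.abs(self.amplitudes) ** 2)
        )


def make_planewave(
    spec: PlaneWaveSpec, n_medium: float
) -> PlaneWaveDecomposition:
    """Singleton decomposition for a plane wave in a homogeneous medium.

    TE/TM are resolved against the plane of incidence of the spec; the
    resulting amplitude is exactly transverse to the propagation direction.
    """
    k_hat = spec.k_hat()
    a_s, a_p = spec.jones() * spec.amplitude
    s_hat, p_hat = polarization_basis(spec.azimuth_deg, k_hat)
    eps = a_s * s_hat + a_p * p_hat
    k = 2 * np.pi * n_medium / spec.wavelength_nm
    return PlaneWaveDecomposition(
        directions=k_hat[None, :], amplitudes=eps[None, :], k=k, n_medium=n_medium
    )
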