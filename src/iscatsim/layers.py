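"""Planar layer stacks, Fresnel coefficients and incident driving fields.

Conventions (fixed package-wide, enforced by tests):

* time dependence ``e^{-i omega t}``; a wave ``e^{+i k z}`` propagates upward;
* the top interface of the stack sits at ``z = 0`` and ``z`` increases upward;
* lengths in nm, angles in degrees at the API surface;
* the TM reflection coefficient is defined *co-oriented*: at normal incidence
  ``r_TM -> (n1 - n2)/(n1 + n2)``, identical to TE.  Textbooks differ on this
  sign; the choice here makes TE and TM degenerate at ``theta = 0``.

The polar angle of a plane wave is signed (anticlockwise positive in the plane
of incidence), so ``theta = -20 deg`` tilts the propagation direction toward
``-x`` for zero azimuth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .materials import Material

__all__ = [
    "LayerStack",
    "PlaneWaveSpec",
    "PlaneWaveComponent",
    "IncidentField",
    "fresnel",
    "stack_rt",
    "brewster_angle",
    "incident_field",
    "polarization_basis",
]

Polarization = Literal["TE", "TM"]


# ---------------------------------------------------------------------------
# layer stack
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerStack:
    """Ordered planar media, listed top to bottom.

    ``interface_z`` holds the interface positions (nm), strictly decreasing,
    with the top interface at ``z = 0`` in the standard configuration.  A
    two-media stack (sample medium above, substrate below) is the common case
    for iSCAT/COBRI.
    """

    materials: tuple[Material, ...]
    interface_z: tuple[float, ...] = (0.0,)

    def __post_init__(self):
        mats = tuple(self.materials)
        zs = tuple(float(z) for z in self.interface_z)
        object.__setattr__(self, "materials", mats)
        object.__setattr__(self, "interface_z", zs)
        if len(mats) < 2:
            raise ValueError("a layer stack needs at least two materials")
        if len(zs) != len(mats) - 1:
            raise ValueError("need exactly len(materials) - 1 interface positions")
        if len(zs) > 1 and np.any(np.diff(zs) >= 0):
            raise ValueError("interface_z must be strictly decreasing (top to bottom)")

    @classmethod
    def two_media(cls, upper: Material, lower: Material) -> "LayerStack":
        """Single interface at ``z = 0``: sample medium above, substrate below."""
        return cls((upper, lower), (0.0,))

    @property
    def top(self) -> Material:
        return self.materials[0]

    @property
    def bottom(self) -> Material:
        return self.materials[-1]

    def indices(self, wavelength_nm: float) -> np.ndarray:
        """Complex refractive index of every medium at ``wavelength_nm``."""
        return np.array(
            [m.refractive_index(wavelength_nm) for m in self.materials], dtype=complex
        )

    def is_matched(self, wavelength_nm: float) -> bool:
        n = self.indices(wavelength_nm)
        return bool(np.allclose(n, n[0]))


# ---------------------------------------------------------------------------
# Fresnel machinery
# ---------------------------------------------------------------------------

def _cos_in_layer(n_layer: complex, n_inc: complex, cos_inc: complex) -> complex:
    """Cosine of the propagation angle in a layer for fixed transverse momentum.

    Branch: ``Im(n cos) >= 0`` so evanescent waves decay away from the
    interface under the ``e^{-i omega t}`` convention.
    """
    s2 = (n_inc / n_layer) ** 2 * (1.0 - cos_inc**2)
    c = np.sqrt(1.0 - s2 + 0j)
    if (n_layer * c).imag < 0:
        c = -c
    return c


def _interface_rt(n1, c1, n2, c2, pol: Polarization):
    """Two-media amplitude coefficients in the co-oriented convention."""
    if pol == "TE":
        den = n1 * c1 + n2 * c2
        return (n1 * c1 - n2 * c2) / den, 2 * n1 * c1 / den
    elif pol == "TM":
        den = n1 * c2 + n2 * c1
        return (n1 * c2 - n2 * c1) / den, 2 * n1 * c1 / den
    raise ValueError(f"polarization must be 'TE' or 'TM', got {pol!r}")


def _parratt(ns, cs, betas, pol: Polarization):
    """Recursive stack coefficients; media ordered along propagation.

    ``betas[j]`` is the one-way phase across medium ``j`` (0 for the two
    semi-infinite end media).  Returns (r, t) referenced at the entry and exit
    interfaces respectively.
    """
    r, t = 0.0 + 0j, 1.0 + 0j
    for j in range(len(ns) - 2, -1, -1):
        r01, t01 = _interface_rt(ns[j], cs[j], ns[j + 1], cs[j + 1], pol)
        ph = np.exp(1j * betas[j + 1])
        den = 1.0 + r01 * r * ph**2
        r, t = (r01 + r * ph**2) / den, t01 * ph * t / den
    return r, t


def stack_rt(
    stack: LayerStack,
    cos_inc,
    pol: Polarization,
    wavelength_nm: float,
    direction: Literal["down", "up"] = "down",
):
    """Stack coefficients for a (possibly complex) incidence-angle cosine.

    Vectorized over ``cos_inc``.  Complex cosines provide the analytic
    continuation used for supercritical-angle transmission.
    """
    n_all = stack.indices(wavelength_nm)
    z = np.asarray(stack.interface_z, dtype=float)
    if direction == "up":
        n_all = n_all[::-1]
        z = z[::-1]
    n_inc = n_all[0]
    c_inc = np.asarray(cos_inc, dtype=complex)
    scalar = c_inc.ndim == 0
    c_inc = np.atleast_1d(c_inc)
    cs = np.array([_cos_in_layer_vec(n, n_inc, c_inc) for n in n_all])
    # preserve an exactly supplied (already-branched) incidence cosine
    cs[0] = c_inc
    k0 = 2 * np.pi / wavelength_nm
    betas = np.zeros((len(n_all),) + c_inc.shape, dtype=complex)
    if len(n_all) > 2:
        d = np.abs(np.diff(z))
        betas[1:-1] = k0 * n_all[1:-1, None] * cs[1:-1] * d[:, None]
    r, t = _parratt(n_all, cs, betas, pol)
    if scalar:
        return complex(r[0]), complex(t[0])
    return r, t


def _cos_in_layer_vec(n_layer, n_inc, cos_inc):
    s2 = (n_inc / n_layer) ** 2 * (1.0 - np.asarray(cos_inc, dtype=complex) ** 2)
    c = np.sqrt(1.0 - s2)
    flip = (n_layer * c).imag < 0
    return np.where(flip, -c, c)


def fresnel(
    stack: LayerStack,
    theta_deg: float,
    pol: Polarization,
    wavelength_nm: float,
    direction: Literal["down", "up"] = "down",
) -> tuple[complex, complex]:
    """Stack reflection and transmission amplitude coefficients.

    ``theta_deg`` is measured in the incidence-side medium: the top medium for
    ``direction='down'`` (light travelling toward -z), the bottom medium for
    ``direction='up'``.  Angles beyond the critical angle are allowed and
    yield evanescent (complex-cosine) transmitted waves.  For a two-media
    stack the result equals the closed-form Fresnel coefficients.
    """
    n_inc = stack.indices(wavelength_nm)[-1 if direction == "up" else 0]
    if abs(n_inc.imag) > 1e-12 and abs(theta_deg) > 1e-12:
        raise ValueError(
            "incidence angle is ill-defined in an absorbing incidence medium"
        )
    c_inc = np.cos(np.deg2rad(theta_deg))
    r, t = stack_rt(stack, c_inc, pol, wavelength_nm, direction)
    return complex(r), complex(t)


def brewster_angle(n_in: float, n_out: float) -> float:
    """TM zero-reflection angle ``arctan(n_out / n_in)`` in degrees."""
    if n_in <= 0 or n_out <= 0:
        raise ValueError("refractive indices must be positive and real")
    return float(np.degrees(np.arctan2(float(n_out), float(n_in))))


# ---------------------------------------------------------------------------
# plane waves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaneWaveSpec:
    """A single incoming plane wave.

    ``polar_angle`` is the signed tilt (degrees) from the vertical axis and
    must satisfy ``|polar_angle| < 90``; ``direction`` selects upward
    (iSCAT-style, impinging on the stack from below) or downward
    (COBRI-style) propagation.  ``polarization`` is ``'TE'``, ``'TM'`` or a
    two-component Jones vector ``(a_TE, a_TM)`` of unit magnitude.
    """

    wavelength_nm: float
    polar_angle_deg: float = 0.0
    azimuth_deg: float = 0.0
    polarization: Polarization | Sequence[complex] = "TM"
    direction: Literal["up", "down"] = "up"
    amplitude: complex = 1.0 + 0j

    def __post_init__(self):
        if not abs(self.polar_angle_deg) < 90:
            raise ValueError("|polar_angle| must be < 90 degrees")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")

    def jones(self) -> np.ndarray:
        """Polarization as a unit-magnitude (a_TE, a_TM) Jones vector."""
        if isinstance(self.polarization, str):
            p = self.polarization.upper()
            if p == "TE":
                return np.array([1.0, 0.0], dtype=complex)
            if p == "TM":
                return np.array([0.0, 1.0], dtype=complex)
            raise ValueError(f"unknown polarization {self.polarization!r}")
        v = np.asarray(self.polarization, dtype=complex)
        if v.shape != (2,):
            raise ValueError("Jones vector must have two components (a_TE, a_TM)")
        norm = np.linalg.norm(v)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("Jones vector must be normalized to unit magnitude")
        return v / norm

    def k_hat(self) -> np.ndarray:
        """Unit propagation direction."""
        th = np.deg2rad(self.polar_angle_deg)
        ph = np.deg2rad(self.azimuth_deg)
        sz = 1.0 if self.direction == "up" else -1.0
        return np.array(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), sz * np.cos(th)]
        )


def polarization_basis(azimuth_deg: float, k_hat: np.ndarray):
    """TE/TM unit vectors for a propagation direction.

    The TE (s) vector is perpendicular to the plane of incidence spanned by
    the vertical axis and the azimuth direction; it is kept independent of
    the polar angle so the basis is continuous through normal incidence for
    signed polar angles.  The TM (p) vector is ``s x k``.
    """
    ph = np.deg2rad(azimuth_deg)
    s_hat = np.array([-np.sin(ph), np.cos(ph), 0.0])
    p_hat = np.cross(s_hat, k_hat)
    return s_hat, p_hat


# ---------------------------------------------------------------------------
# incident (driving) field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaneWaveComponent:
    """One plane-wave term ``E0 e^{i k.r}`` of the driving field."""

    k_vec: np.ndarray      # (3,) complex wavevector, nm^-1
    E0: np.ndarray         # (3,) complex amplitude
    region: Literal["above", "below"]

    def H0(self, k0: float) -> np.ndarray:
        """Scaled magnetic amplitude (Z0 H) from Faraday's law."""
        return np.cross(self.k_vec, self.E0) / k0


class IncidentField:
    """Total driving field of a plane wave impinging on a layer stack.

    Holds the incident + reflected plane waves on the incidence side and the
    transmitted wave on the far side; evaluation at a point selects the
    region by the sign of ``z`` relative to the outer interfaces.  Fields on
    an interface are defined as the limit from the requested region.
    """

    def __init__(self, stack: LayerStack, wave: PlaneWaveSpec):
        self.stack = stack
        self.wave = wave
        self.k0 = 2 * np.pi / wave.wavelength_nm
        self._z_top = stack.interface_z[0]
        self._z_bot = stack.interface_z[-1]
        self.components: list[PlaneWaveComponent] = []
        self._build()

    # -- construction ------------------------------------------------------
    def _build(self):
        wave, stack, k0 = self.wave, self.stack, self.k0
        up = wave.direction == "up"
        inc_region = "below" if up else "above"
        out_region = "above" if up else "below"
        n_inc = (stack.bottom if up else stack.top).refractive_index(wave.wavelength_nm)
        n_out = (stack.top if up else stack.bottom).refractive_index(wave.wavelength_nm)
        z_entry = self._z_bot if up else self._z_top
        z_exit = self._z_top if up else self._z_bot

        k_hat = wave.k_hat()
        a_s, a_p = wave.jones() * wave.amplitude
        s_hat, p_hat = polarization_basis(wave.azimuth_deg, k_hat)
        k_inc = k0 * n_inc * k_hat

        # primary wave
        E_inc = a_s * s_hat + a_p * p_hat
        self.components.append(PlaneWaveComponent(k_inc, E_inc, inc_region))

        r_te, t_te = fresnel(
            stack, wave.polar_angle_deg, "TE", wave.wavelength_nm, wave.direction
        )
        r_tm, t_tm = fresnel(
            stack, wave.polar_angle_deg, "TM", wave.wavelength_nm, wave.direction
        )

        # reflected wave (incidence side); the co-oriented r_TM convention
        # carries a sign flip in the uniform p = s x k basis
        kz = k_inc[2]
        k_ref = np.array([k_inc[0], k_inc[1], -kz], dtype=complex)
        p_ref = np.cross(s_hat, k_ref / (k0 * n_inc))
        ph_r = np.exp(2j * kz * z_entry)
        E_ref = (a_s * r_te * s_hat - a_p * r_tm * p_ref) * ph_r
        self.components.append(PlaneWaveComponent(k_ref, E_ref, inc_region))

        # transmitted wave (far side)
        c_inc = np.cos(np.deg2rad(wave.polar_angle_deg))
        c_out = _cos_in_layer(n_out, n_inc, c_inc)
        sz = 1.0 if up else -1.0
        k_tr = np.array(
            [k_inc[0], k_inc[1], sz * k0 * n_out * c_out], dtype=complex
        )
        p_tr = np.cross(s_hat, k_tr / (k0 * n_out))
        ph_t = np.exp(1j * (kz * z_entry - k_tr[2] * z_exit))
        E_tr = (a_s * t_te * s_hat + a_p * t_tm * p_tr) * ph_t
        self.components.append(PlaneWaveComponent(k_tr, E_tr, out_region))

        self._r = {"TE": r_te, "TM": r_tm}
        self._t = {"TE": t_te, "TM": t_tm}

    # -- evaluation --------------------------------------------------------
    def _region_of(self, z: np.ndarray) -> np.ndarray:
        """'above'-mask for points; interface points count as the upper side."""
        return z >= self._z_top

    def fields(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Electric and scaled magnetic (Z0 H) fields at points (N, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        E = np.zeros(pts.shape, dtype=complex)
        H = np.zeros(pts.shape, dtype=complex)
        above = self._region_of(pts[:, 2])
        inside = (pts[:, 2] < self._z_top) & (pts[:, 2] > self._z_bot) \
            if self._z_top != self._z_bot else np.zeros(len(pts), bool)
        if np.any(inside):
            raise ValueError(
                "field evaluation inside intermediate layers is not supported; "
                "request points above the top or below the bottom interface"
            )
        for comp in self.components:
            mask = above if comp.region == "above" else ~above
            if not np.any(mask):
                continue
            phase = np.exp(1j * pts[mask] @ comp.k_vec)
            E[mask] += phase[:, None] * comp.E0
            H[mask] += phase[:, None] * comp.H0(self.k0)
        return E, H

    def electric(self, points: np.ndarray) -> np.ndarray:
        return self.fields(points)[0]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.electric(points)

    # -- bookkeeping used by the microscopy pipeline -----------------------
    def reflected_component(self) -> PlaneWaveComponent:
        return self.components[1]

    def transmitted_component(self) -> PlaneWaveComponent:
        return self.components[2]

    def coefficient(self, which: Literal["r", "t"], pol: Polarization) -> complex:
        return (self._r if which == "r" else self._t)[pol]


def incident_field(stack: LayerStack, wave: PlaneWaveSpec) -> IncidentField:
    """Build the total driving field (Fresnel-consistent in both regions)."""
    return IncidentField(stack, wave)
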