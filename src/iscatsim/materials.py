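"""Optical materials: constant or tabulated complex permittivity.

All media are non-magnetic (relative permeability fixed at 1).  The time
convention throughout the package is ``e^{-i omega t}``, so passive media have
``Im(eps) >= 0`` and the complex refractive index is ``n + i k`` with
``k >= 0``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Material", "gold", "silver", "water", "glass", "air", "polystyrene"]


def _load_table(name: str) -> np.ndarray:
    """Load a bundled ``wavelength_nm,n,k`` CSV as an (N, 3) array."""
    ref = importlib.resources.files("iscatsim.data") / name
    with ref.open("rb") as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


@dataclass(frozen=True)
class Material:
    """A homogeneous optical medium.

    Parameters
    ----------
    name:
        Label used in configs and diagnostics.
    index:
        Constant (possibly complex) refractive index; mutually exclusive
        with ``table``.
    table:
        ``(N, 3)`` array of ``(wavelength_nm, n, k)`` rows for
        wavelength-dependent media; linear interpolation in wavelength,
        queries outside the tabulated range are rejected.
    """

    name: str
    index: complex | None = None
    table: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if (self.index is None) == (self.table is None):
            raise ValueError("give exactly one of index= or table=")
        if self.index is not None:
            n = complex(self.index)
            if n.real <= 0 or n.imag < 0:
                raise ValueError(f"non-passive or invalid index {n} for {self.name!r}")
        else:
            t = np.asarray(self.table, dtype=float)
            if t.ndim != 2 or t.shape[1] != 3:
                raise ValueError("table must be (N, 3): wavelength_nm, n, k")
            if np.any(np.diff(t[:, 0]) <= 0):
                raise ValueError("table wavelengths must be strictly increasing")
            if np.any(t[:, 2] < 0):
                raise ValueError("extinction coefficient k must be >= 0 (passive medium)")
            object.__setattr__(self, "table", t)

    @classmethod
    def from_csv(cls, name: str, path) -> "Material":
        """Read a ``wavelength_nm,n,k`` CSV (header row required)."""
        return cls(name=name, table=np.loadtxt(path, delimiter=",", skiprows=1))

    def refractive_index(self, wavelength_nm: float) -> complex:
        """Complex refractive index ``n + i k`` at a vacuum wavelength."""
        if self.index is not None:
            return complex(self.index)
        t = self.table
        lo, hi = t[0, 0], t[-1, 0]
        if not (lo <= wavelength_nm <= hi):
            raise ValueError(
                f"{self.name!r}: wavelength {wavelength_nm} nm outside tabulated "
                f"range [{lo}, {hi}] nm"
            )
        n = np.interp(wavelength_nm, t[:, 0], t[:, 1])
        k = np.interp(wavelength_nm, t[:, 0], t[:, 2])
        return complex(n, k)

    def permittivity(self, wavelength_nm: float) -> complex:
        """Relative permittivity ``eps = (n + i k)^2`` at a vacuum wavelength."""
        return self.refractive_index(wavelength_nm) ** 2

    @property
    def is_dispersive(self) -> bool:
        return self.table is not None


def gold() -> Material:
    """Gold, tabulated from the standard published optical-constant compilation."""
    return Material("Au", table=_load_table("au_johnson_christy.csv"))


def silver() -> Material:
    """Silver, tabulated from the standard published optical-constant compilation."""
    return Material("Ag", table=_load_table("ag_johnson_christy.csv"))


def water() -> Material:
    return Material("water", index=1.33)


def glass() -> Material:
    return Material("glass", index=1.5)


def air() -> Material:
    return Material("air", index=1.0)


def polystyrene() -> Material:
    return Material("polystyrene", index=1.59)


_BUILTINS = {
    "au": gold,
    "gold": gold,
    "ag": silver,
    "silver": silver,
    "water": water,
    "glass": glass,
    "air": air,
    "ps": polystyrene,
    "polystyrene": polystyrene,
}


def builtin_material(name: str) -> Material:
    """Look up a built-in material by (case-insensitive) name."""
    try:
        return _BUILTINS[name.lower()]()
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; built-ins: {sorted(set(_BUILTINS))}"
        ) from None
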