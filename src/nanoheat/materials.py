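"""Optical materials: tabulated complex refractive indices.

A material is a table of (wavelength, n, k) rows; the complex index at an
arbitrary wavelength is obtained by linear interpolation of the real and
imaginary parts separately. Gold ships as the Johnson & Christy (1972)
tabulation; silica and water default to the constant indices commonly used
for visible/NIR plasmonics (1.45 and 1.33).
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import RangeError, ValidationError

__all__ = [
    "OpticalMaterial",
    "interpolate_index",
    "gold",
    "silica",
    "water",
    "load_material_csv",
]

#: Wavelength band (nm) every material table must cover.
REQUIRED_BAND = (400.0, 1100.0)


@dataclass(frozen=True)
class OpticalMaterial:
    """Dispersive material defined by a refractive-index table.

    Parameters
    ----------
    name : str
        Label used in error messages and configs.
    wavelengths_nm : ndarray
        Strictly increasing wavelength grid in nm.
    n : ndarray
        Real part of the refractive index at each wavelength.
    k : ndarray
        Imaginary part (extinction coefficient), >= 0.
    """

    name: str
    wavelengths_nm: np.ndarray
    n: np.ndarray
    k: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        n = np.asarray(self.n, dtype=float)
        k = np.asarray(self.k, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValidationError(f"material {self.name!r}: need >= 2 table rows")
        if not (wl.shape == n.shape == k.shape):
            raise ValidationError(f"material {self.name!r}: column length mismatch")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError(
                f"material {self.name!r}: wavelengths must be strictly increasing"
            )
        if np.any(k < 0):
            raise ValidationError(f"material {self.name!r}: k must be >= 0")
        if wl[0] > REQUIRED_BAND[0] or wl[-1] < REQUIRED_BAND[1]:
            raise ValidationError(
                f"material {self.name!r}: table must cover "
                f"{REQUIRED_BAND[0]:.0f}-{REQUIRED_BAND[1]:.0f} nm, "
                f"got {wl[0]:.1f}-{wl[-1]:.1f} nm"
            )
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)

    @classmethod
    def constant(cls, name: str, n: float, k: float = 0.0) -> "OpticalMaterial":
        """Non-dispersive material covering 100 nm - 100 um."""
        wl = np.array([100.0, 1e5])
        return cls(name, wl, np.full(2, float(n)), np.full(2, float(k)))

    def index(self, wavelength_nm):
        """Complex refractive index n + ik at ``wavelength_nm`` (scalar or array)."""
        return interpolate_index(self, wavelength_nm)

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])


def interpolate_index(material: OpticalMaterial, wavelength_nm):
    """Linearly interpolate the complex index of ``material``.

    Raises
    ------
    RangeError
        If any queried wavelength falls outside the tabulated range;
    the message names the material.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    lo, hi = material.range_nm
    if np.any(wl < lo) or np.any(wl > hi):
        raise RangeError(
            f"wavelength {np.min(wl):.1f}-{np.max(wl):.1f} nm outside the "
            f"tabulated range {lo:.1f}-{hi:.1f} nm of material {material.name!r}"
        )
    n = np.interp(wl, material.wavelengths_nm, material.n)
    k = np.interp(wl, material.wavelengths_nm, material.k)
    out = n + 1j * k
    return complex(out) if np.ndim(wavelength_nm) == 0 else out


def load_material_csv(path, name: str | None = None) -> OpticalMaterial:
    """Read a material table from CSV with header ``wavelength_nm,n,k``."""
    df = pd.read_csv(path)
    missing = {"wavelength_nm", "n", "k"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"material CSV {path}: missing column(s) {sorted(missing)}"
        )
    return OpticalMaterial(
        name or str(path),
        df["wavelength_nm"].to_numpy(float),
        df["n"].to_numpy(float),
        df["k"].to_numpy(float),
    )


def gold() -> OpticalMaterial:
    """Johnson & Christy (1972) gold, 342.5-1610 nm."""
    ref = importlib.resources.files("nanoheat.data") / "gold_johnson_christy.csv"
    with importlib.resources.as_file(ref) as path:
        return load_material_csv(path, name="gold (Johnson & Christy)")


def silica(n: float = 1.45) -> OpticalMaterial:
    """Silica core material (constant index, default 1.45)."""
    return OpticalMaterial.constant("silica", n)


def water(n: float = 1.33) -> OpticalMaterial:
    """Water medium (constant index, default 1.33)."""
    return OpticalMaterial.constant("water", n)
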