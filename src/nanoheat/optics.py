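"""Cross-section spectra of solid and core-shell plasmonic particles.

This module ties the material tables to the Mie engine: a
:class:`ParticleSpec` describes the geometry and materials, and
:func:`spectrum` evaluates absorption/scattering/extinction
cross-sections on a wavelength grid in a homogeneous host medium
(water by default). The glass substrate of the experimental assay is
deliberately not modelled; see docs/methods.md.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from . import materials as mat
from .exceptions import GeometryError, ValidationError
from .materials import OpticalMaterial, interpolate_index
from .mie import cross_sections as _cross_sections
from .mie import mie_coated, mie_solid

__all__ = [
    "ParticleSpec",
    "CrossSectionSpectrum",
    "PeakResult",
    "silica_gold_nanoshell",
    "solid_gold_sphere",
    "cross_sections_at",
    "spectrum",
    "peak_wavelength",
    "DEFAULT_GRID",
    "WATER_INDEX",
    "NIR_BAND",
]

#: Default wavelength grid, nm (1 nm step).
DEFAULT_GRID = np.arange(400.0, 1100.0 + 0.5, 1.0)
#: Default host-medium index (water).
WATER_INDEX = 1.33
#: Near-infrared window, nm.
NIR_BAND = (700.0, 1100.0)


@dataclass(frozen=True)
class ParticleSpec:
    """Geometry + material assignment of a spherical nano-heater.

    ``kind`` is ``"solid"`` (homogeneous sphere of ``shell_material``)
    or ``"core_shell"`` (dielectric core of ``core_material`` coated by
    ``shell_material``). Radii in nm.
    """

    kind: Literal["solid", "core_shell"]
    outer_radius_nm: float
    shell_material: OpticalMaterial
    core_radius_nm: float | None = None
    core_material: OpticalMaterial | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("solid", "core_shell"):
            raise ValidationError(f"unknown particle kind {self.kind!r}")
        if not self.outer_radius_nm > 0:
            raise GeometryError(f"outer radius must be > 0, got {self.outer_radius_nm}")
        if self.kind == "core_shell":
            if self.core_radius_nm is None or self.core_material is None:
                raise ValidationError("core_shell requires core_radius_nm and core_material")
            if not 0 < self.core_radius_nm < self.outer_radius_nm:
                raise GeometryError(
                    f"need 0 < core radius < outer radius, got "
                    f"{self.core_radius_nm} vs {self.outer_radius_nm}"
                )

    @property
    def radius_m(self) -> float:
        return self.outer_radius_nm * 1e-9


def silica_gold_nanoshell(core_diameter_nm: float = 120.0,
                          total_diameter_nm: float = 150.0) -> ParticleSpec:
    """NIR-resonant silica-core / gold-shell particle (default 120/150 nm)."""
    return ParticleSpec(
        kind="core_shell",
        outer_radius_nm=total_diameter_nm / 2.0,
        core_radius_nm=core_diameter_nm / 2.0,
        core_material=mat.silica(),
        shell_material=mat.gold(),
        name=f"AuNS {core_diameter_nm:g}/{total_diameter_nm:g} nm",
    )


def solid_gold_sphere(diameter_nm: float) -> ParticleSpec:
    """Solid spherical gold particle of the given diameter."""
    return ParticleSpec(
        kind="solid",
        outer_radius_nm=diameter_nm / 2.0,
        shell_material=mat.gold(),
        name=f"AuNP {diameter_nm:g} nm",
    )


@dataclass(frozen=True)
class CrossSectionSpectrum:
    """Cross-sections (nm²) per wavelength in a fixed medium."""

    wavelengths_nm: np.ndarray
    c_abs_nm2: np.ndarray
    c_sca_nm2: np.ndarray
    c_ext_nm2: np.ndarray
    medium_index: float
    particle_name: str = ""

    def __post_init__(self) -> None:
        for name in ("wavelengths_nm", "c_abs_nm2", "c_sca_nm2", "c_ext_nm2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not (len(self.wavelengths_nm) == len(self.c_abs_nm2)
                == len(self.c_sca_nm2) == len(self.c_ext_nm2)):
            raise ValidationError("spectrum arrays must have equal length")

    def channel(self, which: str) -> np.ndarray:
        try:
            return {"abs": self.c_abs_nm2, "sca": self.c_sca_nm2,
                    "ext": self.c_ext_nm2}[which]
        except KeyError:
            raise ValidationError(f"unknown channel {which!r}; use abs/sca/ext")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "wavelength_nm": self.wavelengths_nm,
            "C_abs_nm2": self.c_abs_nm2,
            "C_sca_nm2": self.c_sca_nm2,
            "C_ext_nm2": self.c_ext_nm2,
        })

    def plot(self, ax=None, channels=("abs", "sca", "ext")):
        """Plot the selected channels; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels = {"abs": "$C_{abs}$", "sca": "$C_{sca}$", "ext": "$C_{ext}$"}
        for ch in channels:
            ax.plot(self.wavelengths_nm, self.channel(ch), label=labels[ch])
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("cross-section (nm$^2$)")
        if self.particle_name:
            ax.set_title(self.particle_name)
        ax.legend()
        return ax


def _relative_indices(particle: ParticleSpec, wavelength_nm: float,
                      medium_index: float):
    m_shell = interpolate_index(particle.shell_material, wavelength_nm) / medium_index
    if particle.kind == "solid":
        return None, m_shell
    m_core = interpolate_index(particle.core_material, wavelength_nm) / medium_index
    return m_core, m_shell


def cross_sections_at(particle: ParticleSpec, wavelength_nm: float,
                      medium_index: float = WATER_INDEX,
                      n_max: int | None = None):
    """(C_abs, C_sca, C_ext) in nm² at a single wavelength."""
    m_core, m_shell = _relative_indices(particle, wavelength_nm, medium_index)
    x_outer = 2.0 * np.pi * medium_index * particle.outer_radius_nm / wavelength_nm
    if particle.kind == "solid":
        coeffs = mie_solid(x_outer, m_shell, n_max=n_max)
    else:
        x_core = 2.0 * np.pi * medium_index * particle.core_radius_nm / wavelength_nm
        coeffs = mie_coated(x_core, x_outer, m_core, m_shell, n_max=n_max)
    return _cross_sections(coeffs, wavelength_nm, medium_index)


def spectrum(particle: ParticleSpec, medium_index: float = WATER_INDEX,
             wavelengths_nm: np.ndarray | None = None) -> CrossSectionSpectrum:
    """Cross-section spectrum of ``particle`` on a wavelength grid.

    Deterministic for fixed inputs; grid must lie inside the material
    tables (default 400-1100 nm, 1 nm step).
    """
    wl = DEFAULT_GRID if wavelengths_nm is None else np.asarray(wavelengths_nm, float)
    out = np.array([cross_sections_at(particle, w, medium_index) for w in wl])
    return CrossSectionSpectrum(wl, out[:, 0], out[:, 1], out[:, 2],
                                medium_index, particle.name)


@dataclass(frozen=True)
class PeakResult:
    """Location of a spectral maximum, parabolically refined."""

    wavelength_nm: float
    value_nm2: float
    channel: str
    on_boundary: bool = False


def peak_wavelength(spec: CrossSectionSpectrum, channel: str = "abs",
                    band: tuple[float, float] | None = None) -> PeakResult:
    """Wavelength of the channel maximum, refined by parabolic interpolation.

    Parameters
    ----------
    spec : CrossSectionSpectrum
    channel : {"abs", "ext", "sca"}
    band : (lo, hi) nm, optional
        Restrict the search, e.g. ``NIR_BAND`` to pick out the
        near-infrared resonance of a nanoshell whose interband maximum
        lies in the visible.

    A maximum on the (possibly band-restricted) grid boundary is
    returned with ``on_boundary=True`` and a warning.
    """
    wl = spec.wavelengths_nm
    y = spec.channel(channel)
    if len(wl) == 0:
        raise ValidationError("empty spectrum")
    if band is not None:
        sel = (wl >= band[0]) & (wl <= band[1])
        if not np.any(sel):
            raise ValidationError(f"band {band} contains no grid points")
        wl, y = wl[sel], y[sel]
    i = int(np.argmax(y))
    if i == 0 or i == len(wl) - 1:
        warnings.warn("spectral maximum lies on the grid boundary; "
                      "peak position not refined", stacklevel=2)
        return PeakResult(float(wl[i]), float(y[i]), channel, on_boundary=True)
    # Parabola through the three points around the grid maximum.
    x0, x1, x2 = wl[i - 1: i + 2]
    y0, y1, y2 = y[i - 1: i + 2]
    denom = (y0 - 2.0 * y1 + y2)
    if denom == 0:
        return PeakResult(float(x1), float(y1), channel)
    # Uniform-grid vertex formula with step h.
    h = 0.5 * (x2 - x0)
    shift = 0.5 * (y0 - y2) / denom * h
    vertex = float(x1 + shift)
    v_val = float(y1 - 0.125 * (y0 - y2) ** 2 / denom)
    return PeakResult(vertex, v_val, channel)
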