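"""Single-particle nanothermometry from melting footprints.

Outside a continuously irradiated nanoparticle the steady-state
temperature rise falls off as the inverse distance from the particle
center,

    dT(D) = C * I / D,

where I is the laser intensity and C a constant bundling the absorption
cross-section, the particle radius and the thermal conductivity of the
surroundings. At the boundary of the melted bilayer footprint the local
temperature equals the lipid melting temperature T_m, so a single
measured footprint radius D_m pins down C:

    C = (T_m - T_ambient) * D_m / I.

The surface temperature rise is dT_P = C * I / R and the experimental
absorption cross-section follows from the point-source heat balance

    C_abs = 4 pi k R dT_P / I  =  4 pi k C,

with k the mean conductivity of the glass/water half-spaces bounding
the supported bilayer.

Internally everything is SI (W/m², m, K); helpers convert from the
W/cm² and µm units in which the measurements arrive.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import EnvironmentError_, FitError, ValidationError

__all__ = [
    "ThermalEnvironment",
    "HeatingModel",
    "HeatingSeries",
    "SlopeFit",
    "fit_C",
    "absorption_cross_section",
    "fit_heating_slope",
    "W_PER_CM2",
]

#: Multiply W/cm² by this to get W/m².
W_PER_CM2 = 1.0e4


@dataclass(frozen=True)
class ThermalEnvironment:
    """Thermal constants of the supported-bilayer assay.

    ``k`` is the simple average of the glass and water conductivities
    (the bilayer sits at the interface of the two half-spaces) unless
    overridden explicitly.
    """

    k_glass: float = 1.1      # W/(m K)
    k_water: float = 0.61     # W/(m K)
    t_m: float = 33.8         # degC, gel->fluid transition of DC15PC
    t_ambient: float = 26.7   # degC
    k_override: float | None = None

    @property
    def k(self) -> float:
        """Combined conductivity, W/(m K)."""
        if self.k_override is not None:
            return self.k_override
        return 0.5 * (self.k_glass + self.k_water)

    @property
    def delta_t_melting(self) -> float:
        """T_m - T_ambient in K."""
        return self.t_m - self.t_ambient


#: Absolute temperature (degC) above which surface-temperature
#: predictions are flagged as beyond the observed regime.
SATURATION_CAP_C = 240.0


@dataclass(frozen=True)
class HeatingModel:
    """Inverse-distance temperature profile of one irradiated particle."""

    c: float                       # K m^3 / W
    radius_m: float
    environment: ThermalEnvironment = field(default_factory=ThermalEnvironment)
    saturation_cap_c: float = SATURATION_CAP_C

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValidationError(f"C must be > 0, got {self.c}")
        if not self.radius_m > 0:
            raise ValidationError(f"radius must be > 0, got {self.radius_m}")

    def temperature_at(self, intensity_W_m2: float, distance_m) -> np.ndarray | float:
        """Temperature rise dT = C I / D (K) at distance(s) D >= R."""
        d = np.asarray(distance_m, dtype=float)
        if np.any(d < self.radius_m):
            raise ValidationError(
                "distance below the particle radius; the 1/D profile is only "
                "valid outside the particle — use surface_temperature() for D = R"
            )
        out = self.c * intensity_W_m2 / d
        return float(out) if np.ndim(distance_m) == 0 else out

    def surface_temperature(self, intensity_W_m2: float) -> tuple[float, bool]:
        """(dT_P in K, saturation flag) at the particle surface D = R.

        The flag marks predictions whose absolute temperature exceeds
        the cap observed for continuously irradiated particles
        (micro-bubble regime); the value is still returned.
        """
        if not intensity_W_m2 > 0:
            raise ValidationError("intensity must be > 0")
        dt_p = self.c * intensity_W_m2 / self.radius_m
        saturated = self.environment.t_ambient + dt_p > self.saturation_cap_c
        return dt_p, saturated

    def c_abs_nm2(self) -> float:
        """Experimental absorption cross-section 4 pi k C, in nm²."""
        return 4.0 * np.pi * self.environment.k * self.c * 1e18


def fit_C(footprint, env: ThermalEnvironment | None = None,
          radius_m: float | None = None) -> HeatingModel:
    """Extract the profile constant C from one footprint measurement.

    ``footprint`` provides ``d_m_um`` (melting radius) and
    ``intensity_W_per_cm2``; at the footprint boundary the temperature
    rise equals ``T_m - T_ambient``, hence
    ``C = (T_m - T_ambient) * D_m / I``.
    """
    env = env or ThermalEnvironment()
    if env.delta_t_melting <= 0:
        raise EnvironmentError_(
            f"T_m ({env.t_m}) must exceed T_ambient ({env.t_ambient})"
        )
    d_m = footprint.d_m_um * 1e-6
    intensity = footprint.intensity_W_per_cm2 * W_PER_CM2
    if not d_m > 0:
        raise ValidationError(f"D_m must be > 0, got {footprint.d_m_um} um")
    if not intensity > 0:
        raise ValidationError("laser intensity must be > 0")
    c = env.delta_t_melting * d_m / intensity
    return HeatingModel(c=c, radius_m=radius_m if radius_m is not None else d_m,
                        environment=env)


def absorption_cross_section(dt_p_K: float, intensity_W_m2: float,
                             radius_m: float,
                             env: ThermalEnvironment | None = None) -> float:
    """Experimental C_abs = 4 pi k R dT_P / I, returned in nm²."""
    env = env or ThermalEnvironment()
    if dt_p_K < 0 or intensity_W_m2 <= 0 or radius_m <= 0:
        raise ValidationError("dT_P must be >= 0 and I, R > 0")
    return 4.0 * np.pi * env.k * radius_m * dt_p_K / intensity_W_m2 * 1e18


@dataclass(frozen=True)
class HeatingSeries:
    """Measured surface-temperature rise vs laser power (or intensity)."""

    power_W: np.ndarray
    dt_K: np.ndarray
    saturation_cap_c: float | None = SATURATION_CAP_C
    t_ambient: float = 26.7

    def __post_init__(self) -> None:
        p = np.asarray(self.power_W, dtype=float)
        t = np.asarray(self.dt_K, dtype=float)
        if p.shape != t.shape or p.ndim != 1:
            raise ValidationError("power and dT must be 1-D arrays of equal length")
        if len(p) < 2:
            raise ValidationError("need at least 2 points")
        if np.any(p <= 0):
            raise ValidationError("powers must be strictly positive")
        object.__setattr__(self, "power_W", p)
        object.__setattr__(self, "dt_K", t)

    @property
    def saturated(self) -> np.ndarray:
        """Boolean mask of points above the absolute-temperature cap."""
        if self.saturation_cap_c is None:
            return np.zeros(len(self.power_W), dtype=bool)
        # >= with a hair of slack so values clipped exactly to the cap
        # (physically saturated measurements) are caught too
        return self.t_ambient + self.dt_K >= self.saturation_cap_c - 1e-9


@dataclass(frozen=True)
class SlopeFit:
    """Result of the zero-intercept heat-conversion fit."""

    slope: float                # K/W (or K per W/m² if intensities given)
    ci95: tuple[float, float]
    stderr: float
    n_used: int
    excluded: np.ndarray        # indices excluded as saturated
    intercept: float = 0.0      # nonzero only in the diagnostic free fit

    def summary(self) -> str:
        lo, hi = self.ci95
        lines = [
            "Heat-conversion fit (zero intercept)" if self.intercept == 0.0
            else "Heat-conversion fit (free intercept, diagnostic)",
            f"  slope    : {self.slope:.4g} K/W  (95% CI {lo:.4g} .. {hi:.4g})",
            f"  std.err. : {self.stderr:.3g}",
            f"  points   : {self.n_used} used, {len(self.excluded)} excluded as saturated",
        ]
        if self.intercept != 0.0:
            lines.insert(2, f"  intercept: {self.intercept:.4g} K")
        return "\n".join(lines)


def fit_heating_slope(series: HeatingSeries, free_intercept: bool = False) -> SlopeFit:
    """OLS fit of dT vs power through the origin.

    The inverse-distance profile predicts strict proportionality, so the
    intercept is fixed at zero by default (``free_intercept=True`` gives
    the diagnostic unconstrained fit). Points whose absolute temperature
    exceeds the saturation cap are excluded from the fit and reported in
    the result, never silently dropped.
    """
    import statsmodels.api as sm

    keep = ~series.saturated
    excluded = np.flatnonzero(~keep)
    x = series.power_W[keep]
    y = series.dt_K[keep]
    if len(x) < (3 if not free_intercept else 4):
        raise FitError(
            f"need >= 3 unsaturated points, have {len(x)} "
            f"({len(excluded)} saturated)"
        )
    if len(excluded):
        warnings.warn(
            f"excluding {len(excluded)} saturated point(s) at indices "
            f"{excluded.tolist()}", stacklevel=2)
    design = sm.add_constant(x) if free_intercept else x[:, None]
    res = sm.OLS(y, design).fit()
    i_slope = 1 if free_intercept else 0
    ci = res.conf_int(alpha=0.05)
    return SlopeFit(
        slope=float(res.params[i_slope]),
        ci95=(float(ci[i_slope][0]), float(ci[i_slope][1])),
        stderr=float(res.bse[i_slope]),
        n_used=len(x),
        excluded=excluded,
        intercept=float(res.params[0]) if free_intercept else 0.0,
    )


def footprints_to_models(footprints: Sequence, radius_m: float,
                         env: ThermalEnvironment | None = None) -> pd.DataFrame:
    """Fit C, dT_P and C_abs for a batch of footprint measurements.

    Returns one row per footprint with columns
    ``C_K_m3_per_W, dT_surface_K, C_abs_nm2, saturated``.
    """
    env = env or ThermalEnvironment()
    rows = []
    for fp in footprints:
        model = fit_C(fp, env, radius_m=radius_m)
        dt_p, saturated = model.surface_temperature(
            fp.intensity_W_per_cm2 * W_PER_CM2)
        rows.append({
            "C_K_m3_per_W": model.c,
            "dT_surface_K": dt_p,
            "C_abs_nm2": model.c_abs_nm2(),
            "saturated": saturated,
        })
    return pd.DataFrame(rows)
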