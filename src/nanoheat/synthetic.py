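"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators emulate the statistical structure the analyses assume:

* fluorescence/reflection frames of an irradiated particle melting a
  disk in a gel-phase bilayer (footprint pipeline),
* 3-D PET uptake phantoms with a whole-tumor ROI, optional necrotic
  core and optional post-treatment cold lesion (response statistic),
* surface-temperature-vs-power series with optional saturation
  (heat-conversion slope fit).

All randomness flows through an explicit per-spec seed; the same seed
reproduces the same output bit for bit. Each generator returns its
ground-truth record alongside the data.

The footprint frame is rendered from the *exact* continuous imaging
model: a hard disk convolved with an isotropic Gaussian PSF has the
closed-form radial profile ``1 - Q1(r/sigma, R/sigma)`` (Marcum Q,
evaluated via the noncentral chi-square CDF), sampled at pixel centers.
With sigma -> 0 this reduces exactly to the two-level disk.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .footprint import DEFAULT_PSF_SIGMA_UM, MicroscopyFrame
from .pet import PETVolume, ROIMask
from .thermometry import (SATURATION_CAP_C, HeatingSeries, ThermalEnvironment,
                          W_PER_CM2)

__all__ = [
    "FootprintScene",
    "PETPhantomSpec",
    "HeatingSeriesSpec",
    "make_footprint_frame",
    "make_footprint_series",
    "make_pet_phantom",
    "make_response_phantom_pair",
    "make_heating_series",
]


# --------------------------------------------------------------------------
# Footprint frames
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FootprintScene:
    """Parameters of one synthetic irradiated-particle frame.

    Intensities are arbitrary camera units; the fluid (melted) level
    must exceed the gel background because the phase-sensitive
    fluorophore partitions into the fluid phase. ``noise`` is
    ``("none",)``, ``("gaussian", sigma)`` or ``("poisson", gain)``.
    """

    d_m_um: float = 2.05
    gel_intensity: float = 100.0
    fluid_intensity: float = 200.0
    psf_sigma_um: float = DEFAULT_PSF_SIGMA_UM
    pixel_size_um: float = 0.08
    shape: tuple[int, int] = (256, 256)
    center_xy: tuple[float, float] | None = None  # pixels; default: near middle
    noise: tuple = ("none",)
    intensity_W_per_cm2: float = 2.7e6
    t_ambient_c: float = 26.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fluid_intensity > self.gel_intensity:
            raise ValidationError("fluid intensity must exceed gel intensity")
        if self.psf_sigma_um < 0:
            raise ValidationError("PSF sigma must be >= 0")
        if self.noise[0] not in ("none", "gaussian", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise[0]!r}")

    def resolved_center(self) -> tuple[float, float]:
        if self.center_xy is not None:
            return self.center_xy
        h, w = self.shape
        # slightly off-grid so sub-pixel recovery is actually exercised
        return ((w - 1) / 2.0 + 0.1, (h - 1) / 2.0 - 0.3)


def _blurred_disk_profile(r_um: np.ndarray, radius_um: float,
                          sigma_um: float) -> np.ndarray:
    """P(point at distance r lands inside the disk after Gaussian blur)."""
    if sigma_um == 0.0:
        return (r_um <= radius_um).astype(float)
    s2 = sigma_um ** 2
    return stats.ncx2.cdf(radius_um ** 2 / s2, df=2, nc=r_um ** 2 / s2)


def make_footprint_frame(scene: FootprintScene):
    """Render one frame; returns ``(MicroscopyFrame, truth dict)``."""
    h, w = scene.shape
    cx, cy = scene.resolved_center()
    half_um = 0.5 * min(h, w) * scene.pixel_size_um
    if scene.d_m_um >= 0.6 * half_um:
        raise ValidationError(
            f"melted footprint D_m = {scene.d_m_um:.2f} um too large for a "
            f"field of half-width {half_um:.2f} um"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    r_um = np.hypot(xx - cx, yy - cy) * scene.pixel_size_um
    fluor = scene.gel_intensity + (
        scene.fluid_intensity - scene.gel_intensity
    ) * _blurred_disk_profile(r_um, scene.d_m_um, scene.psf_sigma_um)

    # reflection: PSF-blurred point emitter at the particle position
    if scene.psf_sigma_um > 0:
        refl = 1000.0 * np.exp(-0.5 * (r_um / scene.psf_sigma_um) ** 2)
    else:
        refl = np.zeros((h, w))
        refl[int(round(cy)), int(round(cx))] = 1000.0

    rng = np.random.default_rng(scene.seed)
    kind = scene.noise[0]
    if kind == "gaussian":
        sigma = float(scene.noise[1])
        fluor = np.clip(fluor + rng.normal(0.0, sigma, fluor.shape), 0.0, None)
        refl = np.clip(refl + rng.normal(0.0, sigma, refl.shape), 0.0, None)
    elif kind == "poisson":
        gain = float(scene.noise[1])
        fluor = rng.poisson(fluor / gain) * gain
        refl = rng.poisson(refl / gain) * gain

    frame = MicroscopyFrame(
        fluorescence=fluor, reflection=refl,
        pixel_size_um=scene.pixel_size_um,
        intensity_W_per_cm2=scene.intensity_W_per_cm2,
        t_ambient_c=scene.t_ambient_c,
    )
    truth = {
        "center_xy": (cx, cy),
        "d_m_um": scene.d_m_um,
        "gel_intensity": scene.gel_intensity,
        "fluid_intensity": scene.fluid_intensity,
        "psf_sigma_um": scene.psf_sigma_um,
        "seed": scene.seed,
    }
    return frame, truth


def make_footprint_series(c_true: float, env: ThermalEnvironment,
                          intensities_W_per_cm2, seed: int = 0,
                          **scene_overrides):
    """One frame per laser intensity with D_m(I) = C I / (T_m - T_ambient).

    Inverts the inverse-distance profile at the melting boundary, so a
    noiseless round trip through the footprint + thermometry pipelines
    must recover ``c_true``. Returns ``(frames, truths)``.
    """
    if env.delta_t_melting <= 0:
        raise ValidationError("T_m must exceed T_ambient")
    frames, truths = [], []
    for i, intensity in enumerate(np.asarray(intensities_W_per_cm2, float)):
        d_m_m = c_true * intensity * W_PER_CM2 / env.delta_t_melting
        scene = FootprintScene(
            d_m_um=d_m_m * 1e6,
            intensity_W_per_cm2=float(intensity),
            t_ambient_c=env.t_ambient,
            seed=seed + i,
            **scene_overrides,
        )
        frame, truth = make_footprint_frame(scene)
        truth["c_true"] = c_true
        frames.append(frame)
        truths.append(truth)
    return frames, truths


# --------------------------------------------------------------------------
# PET phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PETPhantomSpec:
    """Tumor uptake phantom: Gaussian bulk + optional cold subvolumes.

    Geometry mimics the study: a ~700 mm³ ellipsoidal tumor on a
    0.29 x 0.29 x 0.79 mm³ voxel grid. Bulk uptake is normal
    (truncated at 0 by redraw; negligible for mu/sigma >= 4). The
    necrotic core sits at the tumor center, the treatment lesion is
    offset along x; both must lie inside the tumor.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    voxel_dims_mm: tuple[float, float, float] = (0.29, 0.29, 0.79)
    tumor_semiaxes_mm: tuple[float, float, float] = (5.5, 5.5, 5.5)
    bulk_mean: float = 6.0      # %ID/g
    bulk_sd: float = 1.0
    core_radius_mm: float = 0.0
    core_uptake: float = 0.5
    lesion_radius_mm: float = 0.0
    lesion_uptake: float = 0.5
    lesion_offset_mm: tuple[float, float, float] = (2.5, 0.0, 0.0)
    timepoint: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bulk_sd < 0:
            raise ValidationError("bulk sigma must be >= 0")
        if self.core_radius_mm < 0 or self.lesion_radius_mm < 0:
            raise ValidationError("radii must be >= 0")


def _mm_grid(shape, voxel_dims):
    axes = [(np.arange(n) - (n - 1) / 2.0) * d for n, d in zip(shape, voxel_dims)]
    return np.meshgrid(*axes, indexing="ij")


def make_pet_phantom(spec: PETPhantomSpec):
    """Build the phantom; returns ``(PETVolume, ROIMask, truth dict)``."""
    xx, yy, zz = _mm_grid(spec.shape, spec.voxel_dims_mm)
    a, b, c = spec.tumor_semiaxes_mm
    tumor = (xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2 <= 1.0
    if not tumor.any():
        raise ValidationError("tumor ellipsoid contains no voxels")

    rng = np.random.default_rng(spec.seed)
    data = np.zeros(spec.shape)
    n_t = int(tumor.sum())
    vals = rng.normal(spec.bulk_mean, spec.bulk_sd, n_t)
    while np.any(vals < 0):  # truncation at 0 by redraw
        neg = vals < 0
        vals[neg] = rng.normal(spec.bulk_mean, spec.bulk_sd, int(neg.sum()))
    data[tumor] = vals

    voxvol = float(np.prod(spec.voxel_dims_mm))
    truth = {"tumor_volume_mm3": n_t * voxvol, "seed": spec.seed,
             "core_volume_mm3": 0.0, "lesion_volume_mm3": 0.0}

    def _insert_sphere(radius_mm, uptake, offset):
        ox, oy, oz = offset
        inside_tumor = ((ox / a) ** 2 + (oy / b) ** 2 + (oz / c) ** 2) ** 0.5 \
            + radius_mm / min(a, b, c) <= 1.0
        if not inside_tumor:
            raise ValidationError(
                f"sphere of radius {radius_mm} mm at offset {offset} "
                "does not fit inside the tumor"
            )
        mask = (xx - ox) ** 2 + (yy - oy) ** 2 + (zz - oz) ** 2 <= radius_mm ** 2
        data[mask] = uptake
        return int(mask.sum()) * voxvol

    if spec.core_radius_mm > 0:
        truth["core_volume_mm3"] = _insert_sphere(
            spec.core_radius_mm, spec.core_uptake, (0.0, 0.0, 0.0))
    if spec.lesion_radius_mm > 0:
        truth["lesion_volume_mm3"] = _insert_sphere(
            spec.lesion_radius_mm, spec.lesion_uptake, spec.lesion_offset_mm)

    volume = PETVolume(data=data, voxel_dims_mm=spec.voxel_dims_mm,
                       timepoint=spec.timepoint)
    return volume, ROIMask(tumor), truth


def make_response_phantom_pair(seed: int = 0,
                               core_volume_mm3: float = 50.0,
                               lesion_volume_mm3: float = 100.0):
    """Scripted baseline/day-0 phantom pair for the response statistic.

    Baseline carries a necrotic core of ~``core_volume_mm3`` at the
    tumor center. On day 0 the photothermal lesion forms around the
    injection site and envelops the core, so the day-0 cold region is a
    concentric sphere of ~``core + lesion`` mm³; the expected relative
    change in V_low is ``(core + lesion)/core`` (3.0 for the defaults,
    up to voxelization). Returns ``(baseline, day0, roi, truth)``.
    """
    r_core = (3.0 * core_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    r_combined = (3.0 * (core_volume_mm3 + lesion_volume_mm3)
                  / (4.0 * np.pi)) ** (1.0 / 3.0)
    base_spec = PETPhantomSpec(core_radius_mm=r_core, timepoint="baseline",
                               seed=seed)
    day0_spec = PETPhantomSpec(core_radius_mm=r_combined,
                               timepoint="day0", seed=seed + 1)
    baseline, roi, truth_b = make_pet_phantom(base_spec)
    day0, _, truth_d = make_pet_phantom(day0_spec)
    truth = {
        "core_volume_mm3": truth_b["core_volume_mm3"],
        "lesion_volume_mm3": truth_d["core_volume_mm3"]
        - truth_b["core_volume_mm3"],
        "expected_relative_change":
            truth_d["core_volume_mm3"] / truth_b["core_volume_mm3"],
    }
    return baseline, day0, roi, truth


# --------------------------------------------------------------------------
# Heating series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HeatingSeriesSpec:
    """Surface-temperature series dT_P(I) = C I / R + noise, capped."""

    c_true: float = 5.38e-16        # K m^3/W, nanoshell-like
    radius_m: float = 75e-9
    intensities_W_m2: tuple = tuple(np.linspace(0.25e10, 2.5e10, 12))
    noise_sigma_K: float = 0.0
    saturation_cap_c: float | None = SATURATION_CAP_C
    t_ambient_c: float = 26.7
    seed: int = 0

    def __post_init__(self) -> None:
        i = np.asarray(self.intensities_W_m2, float)
        if np.any(i <= 0) or np.any(np.diff(i) <= 0):
            raise ValidationError("intensities must be positive and increasing")
        if self.noise_sigma_K < 0:
            raise ValidationError("noise sigma must be >= 0")


def make_heating_series(spec: HeatingSeriesSpec):
    """Generate the series; returns ``(HeatingSeries, truth dict)``.

    Points whose absolute temperature would exceed the saturation cap
    are clipped to the cap (the physical saturation the fit must
    exclude).
    """
    intens = np.asarray(spec.intensities_W_m2, float)
    rng = np.random.default_rng(spec.seed)
    dt = spec.c_true * intens / spec.radius_m
    if spec.noise_sigma_K > 0:
        dt = dt + rng.normal(0.0, spec.noise_sigma_K, dt.shape)
    n_saturated = 0
    if spec.saturation_cap_c is not None:
        cap_dt = spec.saturation_cap_c - spec.t_ambient_c
        n_saturated = int(np.count_nonzero(dt > cap_dt))
        dt = np.minimum(dt, cap_dt)
    series = HeatingSeries(power_W=intens, dt_K=dt,
                           saturation_cap_c=spec.saturation_cap_c,
                           t_ambient=spec.t_ambient_c)
    truth = {"c_true": spec.c_true, "radius_m": spec.radius_m,
             "slope_true": spec.c_true / spec.radius_m,
             "n_saturated": n_saturated, "seed": spec.seed}
    return series, truth
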