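"""PET-based early photothermal treatment response.

The response statistic is the tumor volume with low or absent
radiotracer uptake: within a whole-tumor ROI, voxels whose uptake
(%ID/g) falls strictly below ``mean - 1.5 * SD`` of the ROI
distribution are counted and converted to mm³ (V_low). Because necrosis
and other factors set a nonzero baseline, each animal's follow-up V_low
is normalized to its own baseline scan.

The threshold is affine-equivariant, so V_low is exactly invariant
under positive affine rescalings of the uptake values — calibration
factors between scans cancel.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "PETVolume",
    "ROIMask",
    "ResponseResult",
    "uptake_stats",
    "low_uptake_volume",
    "relative_change",
    "respond",
    "cohort_summary",
    "percent_id_per_gram",
]


@dataclass(frozen=True)
class PETVolume:
    """3-D uptake volume in %ID/g with voxel dimensions in mm."""

    data: np.ndarray
    voxel_dims_mm: tuple[float, float, float]
    timepoint: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValidationError("PET volume must be 3-D")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValidationError("uptake must be finite and >= 0")
        dims = tuple(float(d) for d in self.voxel_dims_mm)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValidationError(f"voxel dims must be 3 positive values, got {dims}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "voxel_dims_mm", dims)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims_mm))


@dataclass(frozen=True)
class ROIMask:
    """Boolean mask congruent with a PETVolume (whole-tumor ROI)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=bool)
        if arr.ndim != 3:
            raise ValidationError("ROI mask must be 3-D")
        if not arr.any():
            raise ValidationError("ROI mask is empty")
        object.__setattr__(self, "data", arr)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class ResponseResult:
    """Uptake statistics and low-uptake volume for one scan."""

    mean: float
    max: float
    sd: float
    threshold: float
    v_low_mm3: float
    roi_volume_mm3: float
    timepoint: str = ""
    relative_change: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.v_low_mm3 <= self.roi_volume_mm3 + 1e-9:
            raise ValidationError("V_low must lie within [0, ROI volume]")


def _check_congruent(volume: PETVolume, roi: ROIMask) -> None:
    if volume.data.shape != roi.data.shape:
        raise ValidationError(
            f"ROI shape {roi.data.shape} != volume shape {volume.data.shape}"
        )


def uptake_stats(volume: PETVolume, roi: ROIMask,
                 ddof: int = 1) -> tuple[float, float, float]:
    """(mean, max, sd) of %ID/g over the ROI voxels.

    ``sd`` is the sample standard deviation (n-1 denominator) by
    default; set ``ddof=0`` for the population convention.
    """
    _check_congruent(volume, roi)
    vals = volume.data[roi.data]
    sd = float(np.std(vals, ddof=ddof)) if len(vals) > ddof else 0.0
    return float(np.mean(vals)), float(np.max(vals)), sd


def low_uptake_volume(volume: PETVolume, roi: ROIMask,
                      ddof: int = 1) -> ResponseResult:
    """Low-uptake volume V_low: ROI voxels strictly below mean - 1.5 SD.

    Ties at the threshold are excluded (strict inequality). A
    degenerate constant distribution (SD = 0) yields V_low = 0 with a
    warning.
    """
    _check_congruent(volume, roi)
    mean, mx, sd = uptake_stats(volume, roi, ddof=ddof)
    threshold = mean - 1.5 * sd
    if sd == 0.0:
        warnings.warn("degenerate uptake distribution (SD = 0); V_low = 0",
                      stacklevel=2)
        n_low = 0
    else:
        n_low = int(np.count_nonzero(volume.data[roi.data] < threshold))
    vv = volume.voxel_volume_mm3
    return ResponseResult(
        mean=mean, max=mx, sd=sd, threshold=threshold,
        v_low_mm3=n_low * vv, roi_volume_mm3=roi.n_voxels * vv,
        timepoint=volume.timepoint,
    )


def relative_change(result_t: ResponseResult,
                    result_baseline: ResponseResult) -> float:
    """V_low(t) / V_low(baseline)."""
    if result_baseline.v_low_mm3 <= 0:
        raise ValidationError(
            "baseline V_low is zero; the relative change is undefined — "
            "report the absolute V_low instead"
        )
    return result_t.v_low_mm3 / result_baseline.v_low_mm3


def respond(baseline: PETVolume, followups, roi: ROIMask,
            ddof: int = 1) -> list[ResponseResult]:
    """Analyze a baseline + follow-up series against one tumor ROI.

    Returns results for every timepoint (baseline first); follow-up
    results carry ``relative_change`` vs baseline.
    """
    base = low_uptake_volume(baseline, roi, ddof=ddof)
    out = [base]
    for vol in followups:
        res = low_uptake_volume(vol, roi, ddof=ddof)
        rc = relative_change(res, base) if base.v_low_mm3 > 0 else None
        out.append(ResponseResult(**{**res.__dict__, "relative_change": rc}))
    return out


def cohort_summary(changes: pd.DataFrame, value: str = "relative_change",
                   group: str = "group") -> pd.DataFrame:
    """Per-group mean ± SD of per-animal relative changes.

    ``changes`` has one row per animal with a group label. Groups with
    a single animal report SD = 0 and ``sd_undefined = True``. No
    hypothesis testing is performed.
    """
    if len(changes) == 0:
        raise ValidationError("empty cohort table")
    rows = []
    for g, sub in changes.groupby(group, sort=True):
        vals = sub[value].to_numpy(float)
        single = len(vals) < 2
        rows.append({
            group: g,
            "n": len(vals),
            "mean": float(np.mean(vals)),
            "sd": 0.0 if single else float(np.std(vals, ddof=1)),
            "sd_undefined": single,
        })
    return pd.DataFrame(rows)


def percent_id_per_gram(activity_conc_Bq_per_mL: np.ndarray,
                        injected_dose_Bq: float,
                        body_weight_g: float) -> np.ndarray:
    """%ID/g = 100 * (activity concentration / injected dose) * body weight.

    Assumes tissue density 1 g/mL so Bq/mL ~ Bq/g.
    """
    if injected_dose_Bq <= 0 or body_weight_g <= 0:
        raise ValidationError("dose and body weight must be > 0")
    return 100.0 * np.asarray(activity_conc_Bq_per_mL, float) \
        / injected_dose_Bq * body_weight_g
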