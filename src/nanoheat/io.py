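"""Readers/writers for the package's file formats.

Formats: material tables and result tables as CSV, particle and
run configuration as YAML, microscopy frames as TIFF (fluorescence
page, optional reflection page) with a YAML metadata sidecar, PET
volumes and ROI masks as NIfTI (voxel dimensions taken from the
affine). Every reader validates its schema and names the offending
file/field on error.
"""
from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import materials as mat
from .exceptions import ValidationError
from .footprint import FootprintMeasurement, MicroscopyFrame
from .optics import CrossSectionSpectrum, ParticleSpec
from .pet import PETVolume, ROIMask
from .thermometry import ThermalEnvironment

__all__ = [
    "write_spectrum_csv", "read_spectrum_csv",
    "write_footprints_csv", "read_footprints_csv",
    "write_frame_tiff", "read_frame_tiff",
    "write_pet_nifti", "read_pet_nifti", "read_roi_nifti",
    "load_particle_yaml", "load_environment_yaml",
]

FOOTPRINT_COLUMNS = ["file", "center_x", "center_y", "D_m_um", "Tr",
                     "background", "flag_diffraction", "intensity_W_per_cm2"]


# ---------------------------------------------------------------- spectra

def write_spectrum_csv(spec: CrossSectionSpectrum, path) -> None:
    spec.to_dataframe().to_csv(path, index=False)


def read_spectrum_csv(path, medium_index: float = 1.33) -> CrossSectionSpectrum:
    df = pd.read_csv(path)
    req = {"wavelength_nm", "C_abs_nm2", "C_sca_nm2", "C_ext_nm2"}
    missing = req - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    return CrossSectionSpectrum(
        df["wavelength_nm"].to_numpy(), df["C_abs_nm2"].to_numpy(),
        df["C_sca_nm2"].to_numpy(), df["C_ext_nm2"].to_numpy(), medium_index)


# ------------------------------------------------------------- footprints

def write_footprints_csv(measurements, files, path) -> None:
    rows = []
    for fname, m in zip(files, measurements):
        rows.append({
            "file": fname,
            "center_x": m.center_xy[0], "center_y": m.center_xy[1],
            "D_m_um": m.d_m_um, "Tr": m.threshold,
            "background": m.background,
            "flag_diffraction": m.diffraction_limited,
            "intensity_W_per_cm2": m.intensity_W_per_cm2,
        })
    pd.DataFrame(rows, columns=FOOTPRINT_COLUMNS).to_csv(path, index=False)


def read_footprints_csv(path) -> list[FootprintMeasurement]:
    df = pd.read_csv(path)
    missing = set(FOOTPRINT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(FootprintMeasurement(
            center_xy=(float(row["center_x"]), float(row["center_y"])),
            d_m_um=float(row["D_m_um"]), threshold=float(row["Tr"]),
            background=float(row["background"]),
            melted_max=float(row["background"])
            + 2.0 * (float(row["Tr"]) - float(row["background"])),
            diffraction_limited=bool(row["flag_diffraction"]),
            intensity_W_per_cm2=float(row["intensity_W_per_cm2"]),
        ))
    return out


# ------------------------------------------------------------------ TIFF

def write_frame_tiff(frame: MicroscopyFrame, path, sidecar: bool = True) -> None:
    """Write fluorescence (+ optional reflection) pages and a YAML sidecar."""
    path = Path(path)
    if frame.reflection is not None:
        stack = np.stack([frame.fluorescence, frame.reflection]).astype(np.float32)
    else:
        stack = frame.fluorescence.astype(np.float32)
    tifffile.imwrite(path, stack)
    if sidecar:
        meta = {
            "pixel_size_um": float(frame.pixel_size_um),
            "intensity_W_per_cm2": float(frame.intensity_W_per_cm2),
            "t_ambient_C": float(frame.t_ambient_c),
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def read_frame_tiff(path, meta: dict | None = None) -> MicroscopyFrame:
    """Read a frame; metadata from ``meta`` or the YAML sidecar."""
    path = Path(path)
    if meta is None:
        sidecar = path.with_suffix(".yaml")
        if not sidecar.exists():
            raise ValidationError(f"{path}: no metadata given and no sidecar "
                                  f"{sidecar.name} found")
        meta = yaml.safe_load(sidecar.read_text())
    for key in ("pixel_size_um", "intensity_W_per_cm2"):
        if key not in meta:
            raise ValidationError(f"{path}: metadata missing field {key!r}")
    data = tifffile.imread(path)
    if data.ndim == 3:
        if data.shape[0] != 2:
            raise ValidationError(f"{path}: expected 1 or 2 pages, got {data.shape[0]}")
        fluor, refl = data[0], data[1]
    else:
        fluor, refl = data, None
    return MicroscopyFrame(
        fluorescence=np.asarray(fluor, float),
        reflection=None if refl is None else np.asarray(refl, float),
        pixel_size_um=float(meta["pixel_size_um"]),
        intensity_W_per_cm2=float(meta["intensity_W_per_cm2"]),
        t_ambient_c=float(meta.get("t_ambient_C", 26.7)),
    )


# ----------------------------------------------------------------- NIfTI

def write_pet_nifti(volume: PETVolume, path) -> None:
    affine = np.diag(list(volume.voxel_dims_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float64), affine), str(path))


def read_pet_nifti(path, timepoint: str = "") -> PETVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), float)
    zooms = img.header.get_zooms()[:3]
    return PETVolume(data=data, voxel_dims_mm=tuple(float(z) for z in zooms),
                     timepoint=timepoint)


def write_roi_nifti(roi: ROIMask, voxel_dims_mm, path) -> None:
    affine = np.diag(list(voxel_dims_mm) + [1.0])
    nib.save(nib.Nifti1Image(roi.data.astype(np.uint8), affine), str(path))


def read_roi_nifti(path) -> ROIMask:
    img = nib.load(str(path))
    return ROIMask(np.asarray(img.get_fdata()) > 0.5)


# ------------------------------------------------------------------ YAML

_MATERIALS = {"gold": mat.gold, "silica": mat.silica, "water": mat.water}


def _resolve_material(name, base_dir: Path):
    if name in _MATERIALS:
        return _MATERIALS[name]()
    path = base_dir / name
    if path.exists():
        return mat.load_material_csv(path, name=str(name))
    raise ValidationError(
        f"unknown material {name!r}; use one of {sorted(_MATERIALS)} "
        "or a path to a CSV table"
    )


def particle_from_dict(cfg: dict, base_dir=".") -> ParticleSpec:
    base_dir = Path(base_dir)
    known = {"name", "kind", "outer_diameter_nm", "core_diameter_nm",
             "shell_material", "core_material"}
    unknown = set(cfg) - known
    if unknown:
        raise ValidationError(f"particle spec: unknown key(s) {sorted(unknown)}")
    try:
        kind = cfg["kind"]
        outer_r = float(cfg["outer_diameter_nm"]) / 2.0
    except KeyError as exc:
        raise ValidationError(f"particle spec: missing field {exc}")
    shell = _resolve_material(cfg.get("shell_material", "gold"), base_dir)
    kwargs = dict(kind=kind, outer_radius_nm=outer_r, shell_material=shell,
                  name=str(cfg.get("name", "")))
    if kind == "core_shell":
        if "core_diameter_nm" not in cfg:
            raise ValidationError("particle spec: core_shell needs core_diameter_nm")
        kwargs["core_radius_nm"] = float(cfg["core_diameter_nm"]) / 2.0
        kwargs["core_material"] = _resolve_material(
            cfg.get("core_material", "silica"), base_dir)
    return ParticleSpec(**kwargs)


def load_particle_yaml(path) -> ParticleSpec:
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: expected a mapping")
    return particle_from_dict(cfg, base_dir=path.parent)


def load_environment_yaml(path) -> ThermalEnvironment:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    known = {"k_glass", "k_water", "t_m", "t_ambient", "k_override"}
    unknown = set(cfg) - known
    if unknown:
        raise ValidationError(f"{path}: unknown key(s) {sorted(unknown)}")
    return ThermalEnvironment(**{k: float(v) for k, v in cfg.items()})
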