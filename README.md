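# nanoheat

Benchmarking plasmonic nano-heaters for photothermal cancer therapy.

Plasmonic nanoparticles convert near-infrared laser light into intense,
highly localized heat; which particle geometry heats best decides its value
as a photothermal therapy agent. `nanoheat` implements the three
quantitative stages of a single-particle + PET benchmarking platform:

1. **Optics** — analytic Lorenz–Mie absorption/scattering/extinction
   cross-sections for solid gold spheres and silica-core/gold-shell
   particles in water, with numerically stable logarithmic-derivative
   recurrences (no overflow for strongly absorbing metallic shells).
2. **Nanothermometry** — the steady-state temperature profile of a
   continuously irradiated particle falls off as ΔT(D) = C·I/D. A
   temperature-sensitive supported lipid bilayer melts out to the radius
   D_m where the local temperature equals the lipid melting point T_m,
   so one fluorescent "melting footprint" pins down C, the whole profile,
   the particle surface temperature ΔT_P = C·I/R, and the experimental
   absorption cross-section C_abs = 4πkR·ΔT_P/I = 4πkC (k: mean
   glass/water conductivity). The footprint module extracts D_m from
   fluorescence/reflection image pairs by centroid localization,
   rotational averaging, and a 50%-of-maximum-above-background threshold.
3. **PET response** — early treatment response from ¹⁸F-FDG uptake
   volumes: within a whole-tumor ROI, the volume V_low of voxels below
   mean − 1.5·SD of the %ID/g distribution quantifies ablated/metabolically
   silenced tissue; follow-up scans are normalized to baseline.

A seeded synthetic-data module generates ground-truthed microscopy frames,
PET phantoms and heating series, so every stage is testable end to end
without external data.

## Worked example

```python
from nanoheat import optics, synthetic, footprint, thermometry, pet

# 1. theoretical absorption of a 120/150 nm silica-gold nanoshell at 1064 nm
ns = optics.silica_gold_nanoshell()
c_abs, c_sca, c_ext = optics.cross_sections_at(ns, 1064.0)
print(f"{c_abs:.0f} nm^2")                      # -> 2851 nm^2

# 2. melt-footprint thermometry on a synthetic frame (truth D_m = 2.05 um)
frame, truth = synthetic.make_footprint_frame(synthetic.FootprintScene(seed=0))
m = footprint.analyze_frame(frame)
env = thermometry.ThermalEnvironment()          # T_m = 33.8 C, T_amb = 26.7 C
model = thermometry.fit_C(m, env, radius_m=75.65e-9)
dt_p, saturated = model.surface_temperature(m.intensity_W_per_cm2 * 1e4)
print(f"D_m = {m.d_m_um:.3f} um, C = {model.c:.3e} K m^3/W, "
      f"dT_P = {dt_p:.1f} K, C_abs = {model.c_abs_nm2():.0f} nm^2")
# -> D_m = 2.049 um, C = 5.389e-16 K m^3/W, dT_P = 192.3 K, C_abs = 5790 nm^2

# 3. PET response on a scripted baseline/day-0 phantom pair
base, day0, roi, _ = synthetic.make_response_phantom_pair(seed=1)
rb = pet.low_uptake_volume(base, roi)
rd = pet.low_uptake_volume(day0, roi)
print(f"V_low {rb.v_low_mm3:.0f} -> {rd.v_low_mm3:.0f} mm^3, "
      f"relative change {pet.relative_change(rd, rb):.2f}")
# -> V_low 52 -> 148 mm^3, relative change 2.83
```

The surface temperature of ~192 K above ambient at 2.7×10⁶ W/cm² and the
inferred C_abs of ~5.8×10³ nm² are the scale at which a NIR-resonant
nanoshell outperforms solid gold spheres of equal (150 nm) or
EPR-friendlier (80 nm) diameter; the `nanoheat benchmark` command ranks
arbitrary particle specs this way at a chosen therapy wavelength.

## Command line

```bash
nanoheat optics spectrum --particle auns.yaml --out spectrum.csv
nanoheat synth footprint --seed 3 --out synth/
nanoheat footprint analyze synth/frame.tif --out footprints.csv
nanoheat thermo fit --footprints footprints.csv --radius-nm 75 --out heating.csv
nanoheat pet respond --baseline b.nii --followup d0.nii --roi roi.nii --out response.csv
nanoheat benchmark --config config.yaml --out results/
```

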