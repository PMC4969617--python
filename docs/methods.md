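# Methods

## Optical model

Cross-sections are computed from the Lorenz–Mie partial-wave expansion
for a homogeneous sphere and its concentric core–shell generalization.
The implementation follows the numerically stable route of the classic
BHMIE/BHCOAT programs: the logarithmic derivative D_n(z) = ψ′_n/ψ_n is
generated by downward recurrence (upward recurrence diverges for
absorbing media), and all Riccati–Bessel functions of complex argument
enter only through bounded ratios (χ_{n−1}/χ_n, χ_n/ψ_n), so a
strongly absorbing metallic shell never overflows. Series are truncated
at the Wiscombe criterion n_max = ⌈x + 4x^{1/3} + 2⌉; doubling n_max
changes C_abs by < 1e−8 relative over the whole grid (tested). The
sign convention is exp(−iωt) with absorbing indices n + ik, k ≥ 0;
C_abs = C_ext − C_sca, with a negative residual clamped to zero only
within 1e−6 relative (beyond that a convergence error is raised).

The engine is validated three ways, each independent of the recurrence
path: Wiscombe's MIEV0 reference cases to printed precision, a
direct-Bessel-evaluation oracle (scipy spherical Bessel functions at
complex argument), and quasi-static closed forms (Clausius–Mossotti
dipole for the solid sphere, the coated-sphere polarizability for thin
shells). The degenerate checks — identical core/shell indices equals
the solid sphere, vanishing core equals the pure shell material — hold
to ≤ 1e−8 relative.

### Materials and medium

Gold uses the Johnson & Christy (1972) bulk tabulation (packaged as
`data/gold_johnson_christy.csv`, 342.5–1610 nm), linearly interpolated
in n and k separately; silica is the constant 1.45, water 1.33. These
are the community defaults for visible/NIR plasmonics. The particle is
treated as a smooth sphere in an infinite homogeneous water medium: the
glass substrate of the bilayer assay, shell granularity/roughness,
PEG coatings, size dispersion and finite-size corrections to the gold
damping are all outside the model.

**Known consequence.** For the benchmark particles the absolute
absorption cross-sections and their ratios agree with reference
full-wave (FEM) values to better than 5%, but the *resonance positions*
of real, measured particles sit redder than the ideal-sphere
prediction: the computed nanoshell NIR absorption peak is ≈ 753 nm
versus ≈ 799 nm measured by UV-vis for nominal 120/150 nm shells, and
the 150 nm solid sphere extinction peak is ≈ 640 nm versus ≈ 614 nm
measured (the 80 nm sphere, ≈ 549 vs 550 nm, matches). Sensitivity
checks (spline vs linear interpolation of the gold table, water 1.333,
TEM-measured geometry, surface-scattering-corrected shell damping) move
these peaks by < 6 nm, so the gap is a property of the idealized model,
not of the numerics. Peak positions should therefore be read as
ideal-sphere references, not as predictions of a vendor datasheet.

Both absorption and extinction channels are exposed;
UV-vis spectrophotometer comparisons belong to extinction, heating
predictions to absorption. Peak location refines the grid maximum with
a three-point parabola (exact for a locally quadratic spectrum; ≤ 0.1 nm
on the 1 nm default grid); a maximum on the grid/band edge is returned
flagged rather than refined. Because a nanoshell also has an interband
maximum in the visible, the NIR resonance is located by restricting the
search to the 700–1100 nm window.

## Footprint thermometry

Model: a continuously irradiated particle is a point heat source, so
the steady-state temperature rise outside it is ΔT(D) = C·I/D. The
bilayer melts where ΔT = T_m − T_ambient (7.1 K for DC15PC at 33.8 °C
over an ambient of 26.7 °C), giving C = (T_m − T_ambient)·D_m/I from a
single footprint, the surface temperature ΔT_P = C·I/R, and the
experimental absorption cross-section C_abs = 4πk·R·ΔT_P/I ≡ 4πkC with
k = (k_glass + k_water)/2 = 0.855 W/(m·K) (simple average of the two
half-spaces bounding the bilayer; overridable). The C_abs = 4πkC
identity is enforced to 1e−12 relative in the tests. All internal units
are SI; the CLI converts from W/cm² and µm.

Image analysis conventions (fixed because sub-pixel crossings depend on
them): pixel centers at integer (column, row) coordinates, origin at
the top-left pixel center, radii center-to-center. The particle is
located by an intensity-weighted centroid over pixels more than three
robust standard deviations (1.4826·MAD) above the median, on the
reflection channel when available. The radial profile uses 1-pixel
annular bins; the melted-zone maximum is taken from the averaged
profile within 2 µm of the center (noise robustness: averaging before
thresholding); the threshold is background + 50% of (max − background);
D_m is the *first* outward crossing below threshold, linearly
interpolated between bins (robust to peripheral bright debris). The
default background ROI is an annulus at 0.70–0.95 of the field
half-width — several micrometers outside any footprint that fits the
field. The 50% rule makes D_m exactly invariant under positive affine
intensity transforms, and rotation about the particle center moves it
by less than half a pixel (tested).

No PSF deconvolution is applied. Footprints smaller than twice the PSF
width (default σ = 0.21·λ/NA ≈ 73 nm at λ = 488 nm, NA 1.4) are flagged
diffraction-limited instead of corrected; in this regime the recovered
D_m — and hence the inferred surface temperature — is biased upward,
increasingly so as the footprint shrinks (reproduced quantitatively on
synthetic frames). Surface-temperature predictions whose absolute value
exceeds 240 °C are flagged as beyond the observed continuous-wave
regime (micro-bubble formation); the value is still returned.

The heat-conversion slope fit is ordinary least squares through the
origin (the profile model forces ΔT(I=0) = 0; a free-intercept
diagnostic fit is available), with 95% CI from standard regression
theory via statsmodels. Saturated points are excluded and reported,
never silently dropped; with the noise level known, the 3-SE coverage
of the recovered slope is ≥ 99% over 1000 seeded replicates (tested).

## PET response statistic

Uptake statistics are computed over the ROI voxels of each scan
independently (per-image mean and SD, sample convention n−1,
configurable). The response statistic V_low counts voxels strictly
below mean − 1.5·SD and multiplies by the voxel volume from the NIfTI
header; ties at the threshold are excluded. The threshold is
affine-equivariant, so V_low is exactly invariant under uptake → a·uptake + b
(a > 0): calibration factors between scans cancel. Follow-up V_low is
normalized to the animal's baseline; a zero baseline makes the ratio
undefined and is reported as such. Partial-volume effects are not
corrected. Cohort summaries are descriptive (per-group mean ± SD);
hypothesis testing is deliberately out of scope.

A property worth knowing: V_low is *not* monotone in lesion size near
zero. For a pure Gaussian uptake distribution V_low/ROI → Φ(−1.5) ≈
6.68% (the statistic's false-positive floor, reproduced on phantoms
within binomial error). A cold lesion smaller than that tail inflates
the ROI SD, lowers the threshold, and can remove more bulk-tail voxels
than the lesion adds, *decreasing* V_low. Once the lesion dominates the
tail (≳ 7% of the ROI) V_low tracks the lesion volume within 10% and
grows monotonically — which is the regime the baseline-normalized
relative change is designed for.

## Synthetic data

The generators define the test conditions; all randomness flows through
explicit seeds and truth records are returned alongside the data.

* **Footprint frames**: a hard fluid-intensity disk of radius D_m on a
  gel background, imaged through an isotropic Gaussian PSF. The blurred
  disk is rendered from its exact closed form — disk ⊗ Gaussian has
  radial profile 1 − Q₁(r/σ, D_m/σ) (Marcum Q, evaluated via the
  noncentral-χ² CDF) — sampled at pixel centers, so σ → 0 reduces
  exactly to a two-level disk. Defaults: D_m = 2.05 µm, 0.08 µm pixels,
  256² field, gel/fluid levels 100/200, σ_PSF = 73 nm, laser intensity
  2.7×10⁶ W/cm². The reflection channel is a PSF-blurred point at the
  particle position. Noise models: none, additive Gaussian (clipped at
  0), or Poisson with gain. Footprint series invert the profile model,
  D_m(I) = C·I/(T_m − T_ambient), so the full pipeline must round-trip
  C (within 1% noiseless, 5% at SNR 10).
* **PET phantoms**: an ellipsoidal ~700 mm³ tumor (the study's tumor
  size) on a 0.29×0.29×0.79 mm³ voxel grid, bulk uptake Normal(6, 1)
  %ID/g truncated at 0 by redraw (negligible for mean/SD ≥ 4), with an
  optional central necrotic core and an optional cold lesion. The
  scripted baseline/day-0 pair models the photothermal lesion as
  enveloping the injection-site core (a concentric cold sphere of
  core + lesion volume), giving an expected V_low relative change of
  (50+100)/50 = 3 up to voxelization.
* **Heating series**: ΔT_P = C·I/R + Gaussian noise on a 12-point
  intensity grid spanning the single-particle regime
  (2.5×10⁹–2.5×10¹⁰ W/m²), clipped at the 240 °C absolute cap with
  clipped rows flagged saturated.

What passing these tests does *not* show: the frames have no bleaching,
drift, flat-field structure or multi-particle clutter; the phantoms
have no scanner PSF, Poisson sinogram noise or registration error; real
particles deviate from the smooth-sphere optics as described above.

## Problem sizes and numerical defaults

Spectra use the 400–1100 nm grid at 1 nm (701 points; ~0.1 s per
particle). Stochastic checks use 100 seeded frames (footprints), one
~10⁴-voxel phantom per check (PET), and 1000 replicates (slope
coverage) — sizes at which the binomial/CLT bounds quoted above are
sharp. Tie-break and degenerate-input rules: peak on a grid boundary →
flagged, unrefined; SD = 0 in a PET ROI → V_low = 0 with a warning;
uniform image → detection error; melted profile never crossing the
threshold → footprint-exceeds-field error; all-saturated heating series
→ fit error.
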