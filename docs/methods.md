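# Methods

`plumavis` estimates how detectable colorful plumage is to different
viewers — tetrachromatic birds and dichromatic mammalian carnivores — from
reflectance spectra or calibrated multispectral images. This note documents
the models, the conventions chosen where the methodology left choices open,
and what the synthetic-data generators do and do not emulate.

## Receptor-noise-limited contrast

Quantum catch of cone class *r* for patch *p* under illuminant *I* is the
von-Kries-normalized integral

    Q_pr = ∫ I(λ) R_p(λ) S_r(λ) dλ / ∫ I(λ) S_r(λ) dλ

evaluated by trapezoidal quadrature on the union of the input wavelength
grids (so fine-grid inputs lose no resolution). A perfect white reflector
gives Q = 1 for every cone under any illuminant; catches are linear in
reflectance and invariant to uniform illuminant scaling.

Chromatic contrast uses the receptor-noise-limited (RNL) opponent model on
log signals Δ_r = ln Q_rp − ln Q_rq with per-cone noise e_r = w_f/√g_r,
where w_f is the chromatic Weber fraction of the reference cone class
(relative density g = 1):

    ΔS_C² = Σ_{i<j} (Π_{k∉{i,j}} e_k)² (Δ_i − Δ_j)² / Σ_i (Π_{k≠i} e_k)²

For n = 2 this reduces to |Δ_L − Δ_S|/√(e_L² + e_S²); for n = 4 it sums
over all six opponent pairs of the four single cones. Published renderings
of the tetrachromatic formula sometimes carry typographic term
duplications; `plumavis` implements the canonical n-receptor form and
cross-checks it against an explicit six-pair enumeration and the n = 2
closed form in the test suite. Natural logarithms are used throughout (the
conventional choice for the Weber–Fechner log-linear signal). Brightness
contrast is ΔS_L = |ln Q_Lp − ln Q_Lq| / w_f,L on the luminance channel
(avian double cone; the L cone for dichromats, which contribute no S-cone
signal to luminance).

Only the bright-illumination (photopic) regime is modeled: receptor noise
is catch-independent, the best case for detection. Detectability bands:
ΔS ≤ 1 JND below threshold, 1–3 weakly detectable, > 3 detectable.

Preset Weber fractions and densities: peafowl w_f = 0.06 with
g = (0.477, 0.892, 1.047, 1) for (VS, SWS, MWS, LWS) and double-cone
luminance w_f = 0.18; parrot (budgerigar) w_f = 0.105 with
g = (0.25, 0.33, 1.05, 1); carnivoran dichromat w_f = 0.22 for both
channels with g = (0.12, 1). Note that the noise law must carry the square
root of g_r — only e_r = w_f/√g_r reproduces the standard published noise
tuples for these parameter sets, e.g. 0.06/√0.477 = 0.087.

### Sensitivity curves

Measured cone sensitivities (with ocular media and oil-droplet filtering)
are species data the package cannot ship; presets therefore carry
unit-peak Gaussian stand-ins in wavelength (default σ = 40 nm) centered on
published peak wavelengths (peafowl 432/477/537/605 nm; blue-tit-like
UVS 371/448/503/563 nm; ferret-like 430/558 nm). These stand-ins are for
simulation and testing; quantitative work on real data should load measured
curves via `cone_from_csv` or a viewer YAML config. No quantitative claim
in the tests rests on the stand-in shapes — printed scalar checks use only
w_f and g_r, and the image-vs-spectra consistency checks use the same
curves on both paths.

Preset acuities (peafowl 20, parrot 6, carnivoran 9 cycles/degree) are
order-of-magnitude defaults for the species groups and are expected to be
overridden per species from the behavioral literature; they are constructor
arguments, not constants.

## Spectra

Reflectance from raw spectrometer counts is R = (AR − D)/(AR_r − D)
(sample, dark current, white standard), invariant to instrument gain.
Smoothing is Savitzky–Golay over a 20 nm window (rounded to an odd point
count) with polynomial order 2 — the order is a package convention chosen
so that peak shapes survive while shot noise is suppressed. The default
analysis range is 300–700 nm at 1 nm (the range over which PTFE white
standards are certified flat); the bundled CIE D65 daylight table is
tabulated at 10 nm and interpolated linearly, which is immaterial after
von Kries normalization. Boxcar averaging at acquisition time is assumed
already applied by the instrument and is not re-implemented.

## Camera calibration

Pixel values follow the S-log law R(V) = A·exp(−V/T_o) + C, fitted per
channel by nonlinear least squares from a ≥ 4-step grayscale standard
(adjusted R² reported). Linearized values are clipped to [0, 1] after
applying the fitted law; renormalization beyond the fitted C offset is not
performed.

The channel-to-cone mapping regresses each cone catch on the four channel
catches (UV-filter blue + visible R, G, B) with all pairwise interaction
terms, trained on a reflectance library. Two libraries ship:

* `gen_spectra_library` — archetypes plus random 1–3-Gaussian mixtures,
  gamut-spanning; used to demonstrate mapping quality (R² ≥ 0.99 per cone).
* `gen_archetype_library` — jittered leaf/feather archetypes only. When the
  scene is known to contain foliage and plumage, training on the matching
  spectral family is the right calibration (the analog of using a natural-
  spectra database), and makes image-path catches agree with direct
  spectra-path catches to well under 1%.

Mapped catches are floored at 1e-6 before any log operation. Channel
curves for the modified UV camera are user-supplied or synthetic Gaussians
(`gen_camera_channels`); a measured set should be substituted for real
hardware. UV/visible exposure alignment is assumed done upstream.

## Acuity

A viewer with acuity *a* cycles/degree has minimum resolvable angle
1/(2a) degrees, projecting to MRA_mm = 1000·d·tan(MRA) at distance d.
Catch images are blurred with an isotropic Gaussian of
σ_px = k·MRA_mm·px/mm with k = 0.5 by default. The exact filter family
(Gaussian vs disk vs CSF-derived) and its width convention vary across the
literature and are not uniquely determined; the Gaussian/k construction is
this package's documented convention and k is configurable to match
others. Edges use reflective padding to avoid dark-vignette bias in patch
means. Contrast-sensitivity-function filtering is out of scope.

Independent samples for statistics are taken on a square grid spaced one
acuity disk (kernel FWHM = 2.355σ, rounded up to whole pixels). When a
patch is smaller than one disk, the pipeline falls back to the single
pixel nearest the patch centroid — the one look such a viewer gets. For
distance 0 ("no blur") runs the grid spacing defaults to 2 px.

## False color

Renders use √Q tone mapping (an approximation to perceived brightness).
Tetrachromat vision → RGB from LWS/MWS/SWS plus a VS/UVS grayscale;
dichromat vision → B = √Q_S, R = G = √Q_L, so the red−green opponent
signal is zero by construction. Dichromat contrast rescaling works in CIE
L\*a\*b\* (D65, 2° observer): L\* compressed about its image mean by
w_Lh/w_Ld = 0.14/0.22 and the b channel multiplied by w_Ch/w_Cd =
0.06/0.22 ≈ 0.273; results are clipped to sRGB gamut after back-
conversion. Renders are a relative guide to appearance, never a
quantitative detectability measure, and sidecar metadata says so.

## Texture

Granularity analysis decomposes a mean-centered luminance image with ideal
annular FFT bandpass filters on octave band edges (highest edge at the
radial Nyquist corner √0.5 cycles/px, successive edges halving, default 8
bands; the bands partition frequency space exactly, so band images + DC
reconstruct the input). Pattern energy per band is the SD of the filtered
image; ROI shape correction subtracts the spectrum of a mean-filled ROI so
the outline contributes nothing. Summary statistics: total energy,
proportion energy (max/total), and peak filter (band frequency at peak,
ties to the lower frequency; a larger peak frequency means smaller dominant
features). Band-edge conventions differ between granularity
implementations; hard octave annuli are this package's documented choice.

Edge fraction is the proportion of ROI pixels marked by a Canny detector
(σ = 3, high threshold 0.15–0.20 of unit intensity, low threshold fixed at
0.4× the high — the hysteresis ratio is a package convention), after
optional log transform (log(x + 1e-6)) and CLAHE (8×8 tiles, clip limit
0.01). For uncalibrated photographs the green channel serves as the
luminance proxy, and peak filter sizes are normalized by a reference ROI
to compare across photographs taken at unknown distances.

## Statistics

Effect size: 1000 bootstrap resamples draw observation pairs with
replacement and record the mean ΔS_C and ΔS_L; the report is the mean and
SD of resample means (= s.e.m.), with 95% CI = mean ± 2 s.e.m. Grand means
across replicates average replicate means with the s.e.m. taken across
replicates. Significance: one-way PERMANOVA on Euclidean distances among
colorspace coordinates (sw for dichromats, the 4-simplex for
tetrachromats), pseudo-F = (SS_B/(k−1))/(SS_W/(N−k)), null from label
permutation with the add-one p-value convention (p ≥ 1/(n_perm+1)). The
"heterogeneous data" variant of the original analysis ran in proprietary
software; the optional `rank_transform` flag (ranked squared distances) is
a documented approximation, not a reimplementation. A pair can be
statistically significant yet below 1 JND — real but imperceptible — which
is why both numbers are always reported.

## Synthetic data

The generators emulate: archetype reflectances (chlorophyll bump at
550 nm with a red-edge toe; blue structural peak at 455 nm; red long-pass
edge at 605 nm with weak UV; yellow edge at 505 nm with a distinct UV
secondary peak — so yellow > red in 300–400 nm mean reflectance, as for
real carotenoid/psittacofulvin pigments); S-log camera observations with
multiplicative pixel noise; and a concentric three-ring eyespot on a
foliage background rendered per pixel as channel catches with additive
Gaussian noise (default SD 0.005 in reflectance units, a realistic sensor
noise floor) and an optional smooth multiplicative luminance field for
foliage shading. Archetype parameters are fixed documented constants, not
fits to any measured spectrum.

Not emulated: iridescence angle dependence (scene metadata only),
specular highlights, inter-reflection from vegetation, chromatic noise
correlations, lens distortion. Passing tests therefore validate the
computational pipeline and its internal consistency, not the field
accuracy of any particular sensitivity curve or scene model.

Problem sizes used by the default test run were chosen to exercise every
code path at desk scale: 64–256 px images, 60–80-spectrum training
libraries, 200–1000 bootstrap/permutation draws, 400 null simulations for
the type-I-error calibration. All stochastic code takes explicit seeds and
is bit-reproducible.

## Known limitations

* Gaussian stand-in sensitivities ignore oil-droplet cutoff asymmetry;
  real avian curves are steeper on the short-wavelength side.
* Spectral (not just intensity) illuminant changes alter contrasts
  slightly; von Kries normalization gives exact constancy only under
  intensity scaling.
* The channel-to-cone mapping is metamerism-limited: four channels cannot
  encode arbitrary spectra, so accuracy depends on training spectra that
  match the scene's spectral family.
* PERMANOVA assumes exchangeability under the null; strongly unequal
  group dispersions can inflate the error rate (the rank option mitigates,
  not removes, this).
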