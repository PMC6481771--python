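# plumavis

Visual-signal analysis of colorful plumage for the eyes that actually look
at it. Birds see with four chromatic cone classes (VS/UVS, SWS, MWS, LWS)
plus a luminance double cone; the carnivoran mammals that prey on them
(felids, canids, mustelids) are dichromats with only S and L cones. A
feather patch that is blazingly conspicuous to a conspecific bird can
therefore be near-invisible to a fox. `plumavis` quantifies that
difference, for researchers in visual ecology and animal coloration, from
either reflectance spectra or calibrated multispectral photographs.

## What it computes

**Receptor-noise-limited (RNL) contrast.** From an illuminant I(λ), a patch
reflectance R_p(λ) and cone sensitivities S_r(λ), the von-Kries-normalized
quantum catch is

    Q_pr = ∫ I(λ) R_p(λ) S_r(λ) dλ / ∫ I(λ) S_r(λ) dλ

Chromatic contrast between patches p, q is the noise-weighted opponent
distance on log signals Δ_r = ln Q_rp − ln Q_rq, with receptor noise
e_r = w_f/√g_r set by the Weber fraction w_f and relative cone density g_r;
for a dichromat ΔS_C = |Δ_L − Δ_S| / √(e_L² + e_S²), and the general
n-receptor form sums over all opponent cone pairs. Brightness contrast is
ΔS_L = |ln Q_Lp − ln Q_Lq| / w_f,L. Contrasts are in just-noticeable
differences (JND): ≤ 1 below threshold, 1–3 weakly detectable, > 3
readily detectable.

Around this core the package provides, as importable modules and a
`plumavis` command line:

* `spectra` — reflectance from raw spectrometer counts, Savitzky–Golay
  smoothing, resampling, a bundled CIE D65 illuminant
* `viewers` — visual-system presets (peafowl, parrot/UVS, carnivoran
  dichromat) and YAML viewer configs
* `calibration` — S-log camera linearization R(V) = A·e^(−V/T_o) + C fitted
  from a grayscale standard, and the channel→cone-catch mapping with 2-way
  interactions
* `acuity` — distance-dependent Gaussian blur from acuity in cycles/degree,
  and acuity-disk grid sampling for independent observations
* `falsecolor` — √-tone-mapped renders of tetrachromat and dichromat
  percepts, with Weber-ratio contrast rescaling for human display
* `texture` — granularity spectra (octave FFT bandpass pattern energy with
  ROI shape correction) and Canny edge fractions
* `stats` — bootstrap contrast CIs, permutation PERMANOVA, grand means
* `synthetic` — seeded generators for every input the pipeline needs, with
  ground truth

See `docs/methods.md` for model details and conventions.

## Worked example

Contrast of a blue structural-color feather against a green leaf, under
D65 daylight, for a peafowl and a dichromatic predator:

```python
import plumavis as pv
from plumavis.synthetic import gen_reflectance

illum = pv.d65_illuminant()
leaf = gen_reflectance("green_leaf", seed=1)
blue = gen_reflectance("blue_feather", seed=1)
table = pv.run_spectra_pipeline(
    {"green_leaf": [leaf], "blue_feather": [blue]},
    [pv.peafowl_viewer(), pv.dichromat_predator_viewer()],
    illum,
)
print(table[["viewer", "dSc_mean", "dSl_mean", "dSc_detectability"]])
```

prints

```
   patch_p      patch_q             viewer  dSc_mean  dSl_mean dSc_detectability
green_leaf blue_feather            peafowl 30.975162  2.773388        detectable
green_leaf blue_feather dichromat_predator  3.435452  3.454662        detectable
```

The same patch pair is ~31 JND of color for the bird but only ~3.4 JND for
the predator — an order of magnitude of conspicuousness lost to
dichromacy. (With red or yellow feather archetypes the predator's color
contrast drops below 1 JND: effectively invisible chromatically.) The
per-cone receptor noises behind these numbers come straight from the
Weber fractions and densities, e.g.:

```python
pv.receptor_noise(pv.peafowl_viewer())   # [0.087, 0.064, 0.059, 0.060]
pv.receptor_noise(pv.dichromat_predator_viewer())  # [0.635, 0.220]
```

An end-to-end image-path run on a synthetic eyespot scene:

```
plumavis simulate --out fixture --seed 1
plumavis run-all --fixture fixture --out results \
    --viewer dichromat_predator --distances 2,4,8,16
```

which writes a contrast table (per patch pair × distance, with bootstrap
CIs and PERMANOVA p-values), a texture table, and false-color PNG renders.

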