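"""Visual-system definitions and quantum-catch computation.

A viewer is a set of chromatic cone classes (two for a dichromatic mammalian
predator, four for a tetrachromatic bird), a luminance channel (the avian
double cone, or the L cone for dichromats), channel Weber fractions, and a
spatial acuity in cycles per degree.

Quantum catch of a cone for a surface patch is the illuminant-weighted
integral of the patch reflectance against the cone's spectral sensitivity,
divided by the same integral for a perfect white reflector (von Kries
normalization, modeling color constancy):

    Q = integral I(l) R(l) S(l) dl / integral I(l) S(l) dl

Under bright (photopic) illumination, receptor noise for the r-th cone class
is set by the Weber fraction w_f of the reference cone class (relative
density 1) and the relative population density g_r:

    e_r = w_f / sqrt(g_r)

The shipped presets use parametric Gaussian stand-in sensitivity curves with
peak wavelengths from the measured-sensitivity literature for each species
group; users modeling real spectra should load measured curves (including
ocular media and oil-droplet filtering) via `cone_from_csv` or a viewer
config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .spectra import Spectrum, default_grid, read_spectrum_csv, resample

__all__ = [
    "ConeClass",
    "ViewerModel",
    "QuantumCatchVector",
    "gaussian_sensitivity",
    "cone_from_csv",
    "receptor_noise",
    "quantum_catch",
    "catch_vector",
    "normalized_coords",
    "peafowl_viewer",
    "parrot_viewer",
    "dichromat_predator_viewer",
    "load_viewer_config",
    "PRESETS",
]


def gaussian_sensitivity(
    peak_nm: float,
    width_nm: float = 40.0,
    grid_nm: np.ndarray | None = None,
    name: str = "",
) -> Spectrum:
    """Unit-peak Gaussian stand-in for a cone spectral sensitivity curve."""
    if grid_nm is None:
        grid_nm = default_grid()
    grid_nm = np.asarray(grid_nm, dtype=float)
    v = np.exp(-0.5 * ((grid_nm - peak_nm) / width_nm) ** 2)
    return Spectrum(grid_nm, v, kind="sensitivity", name=name or f"gauss{peak_nm:.0f}")


@dataclass(frozen=True)
class ConeClass:
    """A photoreceptor class: name, sensitivity spectrum, relative density g_r."""

    name: str
    sensitivity: Spectrum
    relative_density: float = 1.0

    def __post_init__(self) -> None:
        if self.relative_density <= 0:
            raise ValueError("relative_density must be positive")
        if self.sensitivity.kind != "sensitivity":
            raise ValueError("cone sensitivity spectrum must have kind='sensitivity'")


def cone_from_csv(path, name: str, relative_density: float = 1.0) -> ConeClass:
    """Load a measured cone sensitivity curve from a two-column CSV."""
    s = read_spectrum_csv(path, kind="sensitivity", name=name)
    return ConeClass(name, s, relative_density)


@dataclass(frozen=True)
class ViewerModel:
    """A named visual system.

    ``chromatic_cones`` are ordered short-to-long wavelength; ``luminance_cone``
    is the channel driving brightness perception (avian double cone; the L
    cone for dichromats).  Weber fractions are dimensionless detection
    thresholds; ``acuity_cpd`` is spatial acuity in cycles per degree.
    """

    name: str
    chromatic_cones: tuple[ConeClass, ...]
    luminance_cone: ConeClass
    chromatic_weber: float
    luminance_weber: float
    acuity_cpd: float

    def __post_init__(self) -> None:
        if len(self.chromatic_cones) < 2:
            raise ValueError("a viewer needs at least 2 chromatic cone classes")
        if self.chromatic_weber <= 0 or self.luminance_weber <= 0:
            raise ValueError("Weber fractions must be positive")
        if self.acuity_cpd <= 0:
            raise ValueError("acuity must be positive")
        object.__setattr__(self, "chromatic_cones", tuple(self.chromatic_cones))

    @property
    def n_chromatic(self) -> int:
        return len(self.chromatic_cones)

    @property
    def cone_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromatic_cones)


@dataclass(frozen=True)
class QuantumCatchVector:
    """Von-Kries-normalized chromatic catches (plus luminance) for one patch."""

    viewer: ViewerModel
    Q: np.ndarray
    Q_lum: float
    patch_label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        q = np.asarray(self.Q, dtype=float)
        if q.size != self.viewer.n_chromatic:
            raise ValueError("catch vector length must match viewer cone count")
        if np.any(q <= 0) or self.Q_lum <= 0:
            raise ValueError("quantum catches must be strictly positive")
        object.__setattr__(self, "Q", q)


def receptor_noise(viewer: ViewerModel) -> np.ndarray:
    """Per-chromatic-cone noise e_r = w_f / sqrt(g_r).

    The Weber fraction is referenced to the cone class of relative density 1,
    for which e_r equals w_f exactly.
    """
    g = np.array([c.relative_density for c in viewer.chromatic_cones], dtype=float)
    if np.any(g <= 0):
        raise ValueError("cone relative densities must be positive")
    return viewer.chromatic_weber / np.sqrt(g)


def _common_grid(*specs: Spectrum) -> np.ndarray:
    """Union of the input grids restricted to the overlapping range.

    Keeps every sample node of every input, so integration loses no
    resolution relative to the finest-sampled spectrum.
    """
    lo = max(s.span[0] for s in specs)
    hi = min(s.span[1] for s in specs)
    if hi <= lo:
        raise ValueError("spectra have no overlapping wavelength range")
    grid = np.union1d(
        np.concatenate([s.wavelengths_nm for s in specs]), [lo, hi]
    )
    return grid[(grid >= lo) & (grid <= hi)]


def quantum_catch(illuminant: Spectrum, reflectance: Spectrum, cone: ConeClass) -> float:
    """Von-Kries-normalized quantum catch (ratio of trapezoidal integrals).

    Equals 1 for a perfect white reflector under any illuminant, and is
    linear in the reflectance spectrum.
    """
    grid = _common_grid(illuminant, reflectance, cone.sensitivity)
    i = resample(illuminant, grid).values
    r = resample(reflectance, grid).values
    s = resample(cone.sensitivity, grid).values
    denom = np.trapezoid(i * s, grid)
    if denom <= 0:
        raise ValueError(
            f"cone {cone.name!r}: illuminant and sensitivity do not overlap"
        )
    return float(np.trapezoid(i * r * s, grid) / denom)


def catch_vector(
    illuminant: Spectrum,
    reflectance: Spectrum,
    viewer: ViewerModel,
    patch_label: str = "",
) -> QuantumCatchVector:
    """Chromatic + luminance quantum catches for one patch."""
    q = np.array(
        [quantum_catch(illuminant, reflectance, c) for c in viewer.chromatic_cones]
    )
    q_lum = quantum_catch(illuminant, reflectance, viewer.luminance_cone)
    return QuantumCatchVector(viewer, q, q_lum, patch_label or reflectance.name)


def normalized_coords(qc: QuantumCatchVector) -> np.ndarray:
    """Simplex colorspace coordinates q_p = Q_r / sum_r Q_r (sum to 1).

    For a dichromat the first coordinate is the 1-D colorspace coordinate
    sw = Q_S / (Q_S + Q_L).
    """
    total = qc.Q.sum()
    if total <= 0:
        raise ValueError("degenerate catch vector (non-positive total)")
    return qc.Q / total


# -- presets -----------------------------------------------------------------

def peafowl_viewer(acuity_cpd: float = 20.0) -> ViewerModel:
    """Indian peafowl tetrachromat: VS/SWS/MWS/LWS single cones + double cone.

    Densities g_r = (0.477, 0.892, 1.047, 1); chromatic Weber fraction 0.06
    (chicken color discrimination), double-cone luminance Weber fraction 0.18.
    Sensitivities are Gaussian stand-ins peaking at published peafowl values.
    """
    peaks = {"VS": 432.0, "SWS": 477.0, "MWS": 537.0, "LWS": 605.0}
    dens = {"VS": 0.477, "SWS": 0.892, "MWS": 1.047, "LWS": 1.0}
    cones = tuple(
        ConeClass(n, gaussian_sensitivity(peaks[n], name=f"peafowl_{n}"), dens[n])
        for n in ("VS", "SWS", "MWS", "LWS")
    )
    dbl = ConeClass("DBL", gaussian_sensitivity(567.0, 55.0, name="peafowl_DBL"), 1.0)
    return ViewerModel("peafowl", cones, dbl, 0.06, 0.18, acuity_cpd)


def parrot_viewer(acuity_cpd: float = 6.0) -> ViewerModel:
    """Parrot-like UVS tetrachromat (blue-tit sensitivities as proxy).

    Densities g_r = (0.25, 0.33, 1.05, 1); chromatic Weber fraction 0.105
    (budgerigar), double-cone luminance Weber fraction 0.18.
    """
    peaks = {"UVS": 371.0, "SWS": 448.0, "MWS": 503.0, "LWS": 563.0}
    dens = {"UVS": 0.25, "SWS": 0.33, "MWS": 1.05, "LWS": 1.0}
    cones = tuple(
        ConeClass(n, gaussian_sensitivity(peaks[n], name=f"parrot_{n}"), dens[n])
        for n in ("UVS", "SWS", "MWS", "LWS")
    )
    dbl = ConeClass("DBL", gaussian_sensitivity(563.0, 55.0, name="parrot_DBL"), 1.0)
    return ViewerModel("parrot", cones, dbl, 0.105, 0.18, acuity_cpd)


def dichromat_predator_viewer(acuity_cpd: float = 9.0) -> ViewerModel:
    """Carnivoran dichromat (ferret-like S/L cones; felid/canid proxy).

    Densities g_r = (0.12, 1); both chromatic and luminance Weber fractions
    0.22 (dog brightness discrimination).  Luminance is carried by the L cone
    alone.
    """
    s = ConeClass("S", gaussian_sensitivity(430.0, name="predator_S"), 0.12)
    l = ConeClass("L", gaussian_sensitivity(558.0, name="predator_L"), 1.0)
    return ViewerModel("dichromat_predator", (s, l), l, 0.22, 0.22, acuity_cpd)


PRESETS = {
    "peafowl": peafowl_viewer,
    "parrot": parrot_viewer,
    "dichromat_predator": dichromat_predator_viewer,
}


def load_viewer_config(path) -> ViewerModel:
    """Build a ViewerModel from a YAML config.

    Schema::

        name: my_viewer
        chromatic_weber: 0.06
        luminance_weber: 0.18
        acuity_cpd: 20
        cones:
          - {name: VS, peak_nm: 432, width_nm: 40, density: 0.477}
          - {name: SWS, csv: sws.csv, density: 0.892}
          ...
        luminance_cone: {name: DBL, peak_nm: 567, width_nm: 55}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    def build(entry) -> ConeClass:
        dens = float(entry.get("density", 1.0))
        if "csv" in entry:
            return cone_from_csv(entry["csv"], entry["name"], dens)
        sens = gaussian_sensitivity(
            float(entry["peak_nm"]),
            float(entry.get("width_nm", 40.0)),
            name=entry["name"],
        )
        return ConeClass(entry["name"], sens, dens)

    cones = tuple(build(e) for e in cfg["cones"])
    lum = build(cfg["luminance_cone"]) if "luminance_cone" in cfg else cones[-1]
    return ViewerModel(
        cfg["name"],
        cones,
        lum,
        float(cfg["chromatic_weber"]),
        float(cfg["luminance_weber"]),
        float(cfg["acuity_cpd"]),
    )
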