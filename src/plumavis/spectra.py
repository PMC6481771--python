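"""Spectral data containers and basic operations.

Reflectance, irradiance and sensitivity spectra are all sampled functions of
wavelength on a strictly increasing grid in nanometres.  Reflectance is the
fraction of incident light returned by a surface relative to a diffuse white
standard; values slightly above 1 are tolerated because glossy or iridescent
surfaces can out-reflect a PTFE standard in the specular geometry.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "RawRadianceTriple",
    "DEFAULT_WAVELENGTH_RANGE_NM",
    "DEFAULT_GRID_STEP_NM",
    "default_grid",
    "compute_reflectance",
    "smooth_spectrum",
    "resample",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "d65_illuminant",
]

#: Analysis wavelength range over which the white reflectance standards are
#: certified flat (99.0%), in nm.
DEFAULT_WAVELENGTH_RANGE_NM = (300.0, 700.0)

#: Default common-grid spacing, nm.  Finer than the spectrometer's optical
#: resolution (about 2 nm FWHM), so resampling loses nothing.
DEFAULT_GRID_STEP_NM = 1.0

_KINDS = ("reflectance", "irradiance", "sensitivity")


def default_grid(
    lo: float = DEFAULT_WAVELENGTH_RANGE_NM[0],
    hi: float = DEFAULT_WAVELENGTH_RANGE_NM[1],
    step: float = DEFAULT_GRID_STEP_NM,
) -> np.ndarray:
    """Return the default analysis wavelength grid (inclusive of both ends)."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelengths, nm, length >= 2.
    values : array-like
        Non-negative, finite sample values (same length).
    kind : {'reflectance', 'irradiance', 'sensitivity'}
    name : str, optional
        Free-form label carried through operations.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size or wl.size < 2:
            raise ValueError("wavelengths and values must be 1-D, equal length >= 2")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        if np.any(v < 0):
            raise ValueError("spectrum values must be non-negative")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def with_values(self, values: np.ndarray) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class RawRadianceTriple:
    """Raw spectrometer counts for a sample, white standard and dark current.

    All three are raw count arrays on one shared wavelength grid: ``sample``
    (AR), ``white`` (AR_r) and ``dark`` (D).
    """

    wavelengths_nm: np.ndarray
    sample: np.ndarray
    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        arrs = {}
        for attr in ("sample", "white", "dark"):
            a = np.asarray(getattr(self, attr), dtype=float)
            if a.shape != wl.shape:
                raise ValueError("sample/white/dark must share the wavelength grid")
            arrs[attr] = a
        object.__setattr__(self, "wavelengths_nm", wl)
        for attr, a in arrs.items():
            object.__setattr__(self, attr, a)


def compute_reflectance(raw: RawRadianceTriple, name: str = "") -> Spectrum:
    """Reflectance from raw counts: R(lambda) = (AR - D) / (AR_r - D).

    The dark current is subtracted from both the sample and the white-standard
    radiance, so the result is invariant to the spectrometer's overall gain.

    Raises
    ------
    ValueError
        If the white-minus-dark denominator is not strictly positive
        everywhere (a degenerate white standard).
    """
    denom = raw.white - raw.dark
    if np.any(denom <= 0):
        raise ValueError("white standard counts must exceed dark current everywhere")
    r = (raw.sample - raw.dark) / denom
    return Spectrum(raw.wavelengths_nm, np.clip(r, 0.0, None), kind="reflectance", name=name)


def smooth_spectrum(s: Spectrum, window_nm: float = 20.0, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay smooth over a wavelength interval (default 20 nm).

    The window is converted to the nearest odd number of grid points.  The
    grid and ``kind`` are unchanged; a polynomial of degree <= ``polyorder``
    passes through untouched (up to roundoff).
    """
    step = float(np.median(np.diff(s.wavelengths_nm)))
    n = int(round(window_nm / step))
    if n % 2 == 0:
        n += 1
    if n < polyorder + 2:
        raise ValueError(
            f"window of {window_nm} nm spans only {n} points; need >= polyorder+2"
        )
    if n > len(s):
        raise ValueError("smoothing window longer than the spectrum")
    sm = savgol_filter(s.values, window_length=n, polyorder=polyorder)
    return s.with_values(np.clip(sm, 0.0, None))


def resample(s: Spectrum, grid_nm: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``grid_nm``; extrapolation is refused."""
    grid = np.asarray(grid_nm, dtype=float)
    lo, hi = s.span
    if grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9:
        raise ValueError(
            f"target grid [{grid[0]}, {grid[-1]}] outside source span [{lo}, {hi}]"
        )
    v = np.interp(grid, s.wavelengths_nm, s.values)
    return Spectrum(grid, v, kind=s.kind, name=s.name)


# -- CSV I/O -----------------------------------------------------------------

def read_spectrum_csv(path, kind: str = "reflectance", name: str = "") -> Spectrum:
    """Read a two-column CSV with header ``wavelength_nm,value``."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if "wavelength_nm" in cols:
        wl = df[df.columns[cols.index("wavelength_nm")]].to_numpy(float)
        v = df[df.columns[cols.index("value")]].to_numpy(float)
    else:  # tolerate headerless two-column files
        df = pd.read_csv(path, header=None)
        wl = df.iloc[:, 0].to_numpy(float)
        v = df.iloc[:, 1].to_numpy(float)
    return Spectrum(wl, v, kind=kind, name=name or str(path))


def write_spectrum_csv(s: Spectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": s.wavelengths_nm, "value": s.values}).to_csv(
        path, index=False
    )


def d65_illuminant(grid_nm: np.ndarray | None = None) -> Spectrum:
    """The CIE D65 daylight illuminant (relative SPD, 100 at 560 nm).

    The packaged table is tabulated at 10 nm over 300-780 nm and linearly
    interpolated onto ``grid_nm`` (default analysis grid).  Quantum catches
    are von-Kries normalized downstream, so the absolute scale is arbitrary.
    """
    ref = importlib.resources.files("plumavis.data") / "cie_d65.csv"
    with importlib.resources.as_file(ref) as p:
        s = read_spectrum_csv(p, kind="irradiance", name="CIE D65")
    if grid_nm is None:
        grid_nm = default_grid()
    return resample(s, grid_nm)
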