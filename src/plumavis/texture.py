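"""Visual-texture analysis: granularity spectra and edge fractions.

Granularity analysis decomposes a luminance image into octave spatial-
frequency bands with ideal (hard-annulus) FFT bandpass filters.  The
"pattern energy" of a band is the standard deviation of the band-filtered
image; pattern energy vs band is the granularity spectrum.  To remove the
contribution of the region-of-interest outline itself, the spectrum of a
"mean-masked" image (ROI filled with its own mean) is subtracted from that
of the masked image, leaving a shape-independent spectrum.  Summary
statistics: total energy (overall pattern contrast), proportion energy
(dominance of the most prevalent feature scale), and peak filter (the
spatial frequency at peak energy — higher peak frequency means smaller
dominant features).

Edge fraction is a complementary complexity measure: the proportion of ROI
pixels flagged by a Canny detector, optionally after log transform and
contrast-limited adaptive histogram equalization (CLAHE) so that edges are
found evenly across regions of widely differing illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.exposure import equalize_adapthist
from skimage.feature import canny

__all__ = [
    "GranularitySpectrum",
    "TextureStats",
    "roi_mask_from_polygon",
    "bandpass_stack",
    "band_edges_cycles_per_px",
    "granularity_spectrum",
    "summarize",
    "edge_fraction",
    "green_channel_luminance",
    "normalize_peak_filter",
]

#: Default number of octave granularity bands.
DEFAULT_N_BANDS = 8

#: Canny hysteresis: low threshold as a fraction of the high threshold.
CANNY_LOW_FRACTION = 0.4


@dataclass(frozen=True)
class GranularitySpectrum:
    """Pattern energy per ascending spatial-frequency band.

    ``bands`` are band-center frequencies in cycles/pixel; ``energy`` is in
    intensity-SD units.  ``normalized_energy`` is energy/total (zeros when
    the total is zero).
    """

    bands: np.ndarray
    energy: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bands, dtype=float)
        e = np.asarray(self.energy, dtype=float)
        if b.size != e.size or b.size < 2:
            raise ValueError("bands and energy must match, length >= 2")
        if np.any(np.diff(b) <= 0):
            raise ValueError("band centers must be ascending")
        if np.any(e < 0):
            raise ValueError("energies must be non-negative")
        object.__setattr__(self, "bands", b)
        object.__setattr__(self, "energy", e)

    @property
    def total_energy(self) -> float:
        return float(self.energy.sum())

    @property
    def normalized_energy(self) -> np.ndarray:
        t = self.total_energy
        return self.energy / t if t > 0 else np.zeros_like(self.energy)


@dataclass(frozen=True)
class TextureStats:
    """Granularity summary statistics plus edge fraction."""

    total_energy: float
    proportion_energy: float
    peak_filter: float  # band-center frequency at peak energy, cycles/px
    edge_fraction: float = float("nan")
    defined: bool = True


def roi_mask_from_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask from (row, col) polygon vertices."""
    v = np.asarray(vertices, dtype=float)
    rr, cc = draw_polygon(v[:, 0], v[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        raise ValueError("polygon encloses no pixels")
    return mask


def band_edges_cycles_per_px(shape: tuple[int, int], n_bands: int) -> np.ndarray:
    """Ascending octave band edges in cycles/pixel, length n_bands + 1.

    The highest edge is the radial Nyquist corner sqrt(0.5); successive
    edges halve; the lowest band extends down to (but not including) zero.
    """
    r_max = np.sqrt(0.5)
    edges = [0.0] + [r_max / 2 ** (n_bands - 1 - i) for i in range(n_bands)]
    return np.asarray(edges)


def _radial_frequency(shape: tuple[int, int]) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    return np.sqrt(fy**2 + fx**2)


def bandpass_stack(image: np.ndarray, n_bands: int = DEFAULT_N_BANDS) -> list[np.ndarray]:
    """Ideal annular FFT bandpass decomposition into octave bands.

    The image is mean-centered internally; bands partition all nonzero
    frequencies, so the band images plus the DC mean sum back to the
    original exactly (to FFT roundoff).  Returned lowest frequency first.
    """
    img = np.asarray(image, dtype=float)
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if min(img.shape) < 2**n_bands:
        raise ValueError(
            f"image of shape {img.shape} too small for {n_bands} octave bands"
        )
    mean = img.mean()
    F = np.fft.fft2(img - mean)
    r = _radial_frequency(img.shape)
    edges = band_edges_cycles_per_px(img.shape, n_bands)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (r > lo) & (r <= hi)
        out.append(np.real(np.fft.ifft2(F * mask)))
    return out


def _band_centers(shape: tuple[int, int], n_bands: int) -> np.ndarray:
    edges = band_edges_cycles_per_px(shape, n_bands)
    lo = edges[:-1].copy()
    lo[0] = edges[1] / 2.0  # geometric center for the open lowest band
    return np.sqrt(lo * edges[1:])


def granularity_spectrum(
    image: np.ndarray,
    roi: np.ndarray | None = None,
    n_bands: int = DEFAULT_N_BANDS,
) -> GranularitySpectrum:
    """Shape-corrected granularity spectrum of an ROI.

    Pattern energy per band is SD(filtered masked image) minus SD(filtered
    mean-masked image), floored at zero: the mean-masked term carries the
    ROI outline's own spectral content, so a featureless ROI of any shape
    scores zero in every band.
    """
    img = np.asarray(image, dtype=float)
    if roi is None:
        mask = np.ones(img.shape, dtype=bool)
    else:
        mask = np.asarray(roi, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError("ROI mask must match the image shape")
    if mask.sum() <= 1:
        raise ValueError("ROI must contain more than one pixel")

    masked = np.where(mask, img, 0.0)
    mean_masked = np.where(mask, img[mask].mean(), 0.0)
    stack_m = bandpass_stack(masked, n_bands)
    stack_mm = bandpass_stack(mean_masked, n_bands)
    energy = np.array(
        [max(bm.std() - bmm.std(), 0.0) for bm, bmm in zip(stack_m, stack_mm)]
    )
    return GranularitySpectrum(_band_centers(img.shape, n_bands), energy)


def summarize(spec: GranularitySpectrum) -> TextureStats:
    """Total energy, proportion energy and peak filter frequency.

    An all-zero spectrum yields ``defined=False`` with NaN proportion/peak
    rather than raising.  Peak ties break toward the lower frequency.
    """
    total = spec.total_energy
    if total <= 0:
        return TextureStats(0.0, float("nan"), float("nan"), defined=False)
    peak_idx = int(np.argmax(spec.energy))  # argmax returns first (lowest-f) max
    return TextureStats(
        total_energy=total,
        proportion_energy=float(spec.energy[peak_idx] / total),
        peak_filter=float(spec.bands[peak_idx]),
    )


def edge_fraction(
    image: np.ndarray,
    roi: np.ndarray | None = None,
    sigma: float = 3.0,
    threshold: float = 0.15,
    preprocess: bool = True,
) -> float:
    """Fraction of ROI pixels flagged as edges by a Canny detector.

    ``threshold`` is the Canny high threshold relative to maximum intensity
    1 (recommended range 0.15-0.20); the low threshold is 0.4x the high.
    With ``preprocess``, the image is log transformed (log(x + 1e-6)) and
    CLAHE-equalized first.
    """
    img = np.asarray(image, dtype=float)
    if roi is None:
        mask = np.ones(img.shape, dtype=bool)
    else:
        mask = np.asarray(roi, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError("ROI mask must match the image shape")
    if np.ptp(img) < 1e-12:
        return 0.0
    if np.any(img < 0):
        raise ValueError("image must be non-negative")
    work = img / img.max()
    if preprocess:
        work = np.log(work + 1e-6)
        work = (work - work.min()) / np.ptp(work)
        work = equalize_adapthist(work, clip_limit=0.01)
    edges = canny(
        work,
        sigma=sigma,
        low_threshold=CANNY_LOW_FRACTION * threshold,
        high_threshold=threshold,
    )
    return float(edges[mask].mean())


def green_channel_luminance(rgb: np.ndarray) -> np.ndarray:
    """Green channel of an RGB photograph as a float luminance proxy.

    Camera green channels approximate the L-cone spectral sensitivity, so
    the green channel stands in for luminance when no calibration exists.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return arr[..., 1]


def normalize_peak_filter(
    stats: dict[str, TextureStats], reference: str
) -> dict[str, float]:
    """Peak filter frequencies divided by a reference ROI's peak.

    The reference (e.g. the bird's train) maps to 1; this removes the
    dependence of absolute spatial frequency on photographic distance.
    """
    if reference not in stats:
        raise KeyError(f"reference ROI {reference!r} not in stats")
    ref = stats[reference]
    if not ref.defined or not np.isfinite(ref.peak_filter) or ref.peak_filter <= 0:
        raise ValueError("reference ROI has no defined granularity peak")
    return {
        label: (s.peak_filter / ref.peak_filter if s.defined else float("nan"))
        for label, s in stats.items()
    }
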