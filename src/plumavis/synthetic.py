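"""Synthetic inputs with known ground truth for the whole pipeline.

Generators for feather/foliage reflectance archetypes, Gaussian cone and
camera-channel sensitivity curves, grayscale-standard camera observations
following the S-log law, patterned multispectral scenes (a concentric
eyespot on a foliage-like background), and texture test images.  Every
generator is deterministic for a fixed seed, and the ground truth (patch
spectra, S-log parameters, patch maps) is returned alongside the data so
recovery and consistency tests can close the loop.

Archetype spectral shapes emulate the qualitative features of real
plumage/foliage reflectances: a chlorophyll green peak near 550 nm, a blue
structural-color peak near 455 nm, a red long-pass edge near 605 nm with
weak UV, and a yellow edge near 505 nm with a distinct UV secondary peak
(carotenoid/psittacofulvin-like).  Their parameters are fixed documented
constants, not fits to any measured spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibration import CHANNELS, GrayscaleStandard, MultispectralImage, SlogParams, invert_slog
from .spectra import Spectrum, default_grid
from .viewers import ConeClass, gaussian_sensitivity, quantum_catch

__all__ = [
    "SceneSpec",
    "ARCHETYPES",
    "gen_cone_set",
    "gen_reflectance",
    "gen_spectra_library",
    "gen_archetype_library",
    "gen_camera_channels",
    "gen_grayscale_observations",
    "gen_scene",
    "gen_texture_image",
]

ARCHETYPES = ("green_leaf", "blue_feather", "red_feather", "yellow_feather", "flat_gray")


def gen_cone_set(
    peaks_nm: list[float],
    widths_nm: list[float],
    names: list[str] | None = None,
    densities: list[float] | None = None,
    grid_nm: np.ndarray | None = None,
) -> list[ConeClass]:
    """Unit-peak Gaussian cone classes at the given peaks/widths."""
    if len(peaks_nm) != len(widths_nm):
        raise ValueError("peaks and widths must have equal length")
    names = names or [f"cone{i}" for i in range(len(peaks_nm))]
    densities = densities or [1.0] * len(peaks_nm)
    return [
        ConeClass(n, gaussian_sensitivity(p, w, grid_nm, name=n), d)
        for n, p, w, d in zip(names, peaks_nm, widths_nm, densities)
    ]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gen_reflectance(
    archetype: str,
    seed: int | None = None,
    level: float = 0.5,
    grid_nm: np.ndarray | None = None,
) -> Spectrum:
    """A smooth reflectance spectrum with an archetype's qualitative features.

    ``seed`` adds a small (+/- ~10%) reproducible amplitude jitter so that a
    library of distinct but same-family spectra can be drawn; ``level`` is
    the constant for ``flat_gray``.
    """
    if grid_nm is None:
        grid_nm = default_grid()
    wl = np.asarray(grid_nm, dtype=float)
    rng = np.random.default_rng(seed)
    jitter = 1.0 + 0.1 * rng.standard_normal(3) if seed is not None else np.ones(3)

    if archetype == "flat_gray":
        v = np.full_like(wl, level)
    elif archetype == "green_leaf":
        v = 0.04 + 0.14 * jitter[0] * np.exp(-0.5 * ((wl - 550.0) / 40.0) ** 2)
        v += 0.02 * jitter[1] * _sigmoid((wl - 690.0) / 10.0)  # red-edge toe
    elif archetype == "blue_feather":
        v = 0.03 + 0.32 * jitter[0] * np.exp(-0.5 * ((wl - 455.0) / 35.0) ** 2)
    elif archetype == "red_feather":
        v = 0.03 + 0.55 * jitter[0] * _sigmoid((wl - 605.0) / 18.0)
        v += 0.04 * jitter[1] * np.exp(-0.5 * ((wl - 350.0) / 30.0) ** 2)
    elif archetype == "yellow_feather":
        v = 0.04 + 0.58 * jitter[0] * _sigmoid((wl - 505.0) / 22.0)
        # distinct UV secondary peak: yellow pigments reflect far more UV
        # than red ones do
        v += 0.14 * jitter[1] * np.exp(-0.5 * ((wl - 350.0) / 32.0) ** 2)
    else:
        raise ValueError(f"unknown archetype {archetype!r}; choose from {ARCHETYPES}")
    return Spectrum(wl, np.clip(v, 1e-4, None), kind="reflectance", name=archetype)


def gen_spectra_library(
    n: int = 80,
    seed: int = 0,
    grid_nm: np.ndarray | None = None,
) -> list[Spectrum]:
    """A gamut-spanning library of smooth natural-like reflectance spectra.

    Mixtures of 1-3 Gaussians in wavelength on a low baseline, plus the
    feather/leaf archetypes; used to train the channel-to-cone mapping.
    """
    if grid_nm is None:
        grid_nm = default_grid()
    wl = np.asarray(grid_nm, dtype=float)
    rng = np.random.default_rng(seed)
    lib: list[Spectrum] = [
        gen_reflectance(a, seed=int(rng.integers(2**31)), grid_nm=wl)
        for a in ("green_leaf", "blue_feather", "red_feather", "yellow_feather")
    ]
    lib.append(gen_reflectance("flat_gray", level=0.5, grid_nm=wl))
    while len(lib) < n:
        k = rng.integers(1, 4)
        v = np.full_like(wl, rng.uniform(0.01, 0.15))
        for _ in range(k):
            peak = rng.uniform(wl[0], wl[-1])
            width = rng.uniform(20.0, 90.0)
            amp = rng.uniform(0.05, 0.8)
            v += amp * np.exp(-0.5 * ((wl - peak) / width) ** 2)
        lib.append(
            Spectrum(wl, np.clip(v, 1e-4, 1.1), kind="reflectance", name=f"mix{len(lib)}")
        )
    return lib[:n]


def gen_archetype_library(
    n: int = 80,
    seed: int = 0,
    archetypes: tuple[str, ...] = (
        "green_leaf",
        "blue_feather",
        "red_feather",
        "yellow_feather",
    ),
    grid_nm: np.ndarray | None = None,
) -> list[Spectrum]:
    """Jittered draws from the leaf/feather archetype families only.

    This is the training library to use when the imaged scene is known to
    contain foliage and plumage: the channel-to-cone mapping is then trained
    on spectra representative of what the camera actually sees, mirroring
    the use of a natural-spectra database for calibration.
    """
    rng = np.random.default_rng(seed)
    return [
        gen_reflectance(
            archetypes[i % len(archetypes)], seed=int(rng.integers(2**31)), grid_nm=grid_nm
        )
        for i in range(n)
    ]


def gen_camera_channels(grid_nm: np.ndarray | None = None) -> dict[str, Spectrum]:
    """Plausible sensitivity curves for a UV-capable modified camera.

    A UV-filter blue channel peaking near 360 nm plus visible R, G, B
    channels; Gaussian shapes standing in for measured curves.
    """
    peaks = {"uv_b": (360.0, 35.0), "vis_r": (600.0, 50.0),
             "vis_g": (535.0, 45.0), "vis_b": (460.0, 40.0)}
    return {
        name: gaussian_sensitivity(p, w, grid_nm, name=name)
        for name, (p, w) in peaks.items()
    }


def gen_grayscale_observations(
    params: SlogParams,
    reflectances: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    channels: tuple[str, ...] = CHANNELS,
) -> GrayscaleStandard:
    """Camera pixel values for known grayscale steps via the inverted S-log law.

    V = -T_o ln((R - C)/A), with multiplicative Gaussian noise of relative
    standard deviation ``noise_sd`` added independently per channel.
    """
    r = np.asarray(reflectances, dtype=float)
    v = invert_slog(params, r)
    rng = np.random.default_rng(seed)
    pixel_values = {}
    for ch in channels:
        noisy = v * (1.0 + noise_sd * rng.standard_normal(v.shape)) if noise_sd > 0 else v
        pixel_values[ch] = noisy
    return GrayscaleStandard(r, pixel_values)


@dataclass(frozen=True)
class SceneSpec:
    """Layout of a synthetic eyespot-on-foliage multispectral scene.

    ``rings`` are (label, radius fraction of the short image side) from the
    innermost patch outward, drawn as concentric disks about the image
    center; everything else is ``background``.  ``region_archetypes`` maps
    labels to reflectance archetypes.  ``noise_sd`` is additive Gaussian
    channel noise in linearized-reflectance units (clipped at 0);
    ``texture_amp`` modulates the background with a smooth multiplicative
    foliage-like field.
    """

    size_px: tuple[int, int] = (96, 96)
    px_per_mm: float = 5.0
    rings: tuple[tuple[str, float], ...] = (
        ("eyespot_center", 0.10),
        ("eyespot_inner", 0.20),
        ("eyespot_outer", 0.30),
    )
    background: str = "foliage"
    region_archetypes: dict = field(
        default_factory=lambda: {
            "eyespot_center": "blue_feather",
            "eyespot_inner": "yellow_feather",
            "eyespot_outer": "red_feather",
            "foliage": "green_leaf",
        }
    )
    noise_sd: float = 0.005
    texture_amp: float = 0.0
    seed: int = 0


def gen_scene(
    spec: SceneSpec,
    channel_sensitivities: dict[str, Spectrum],
    illuminant: Spectrum,
) -> tuple[MultispectralImage, np.ndarray, dict[str, Spectrum]]:
    """Render a multispectral eyespot scene with known ground truth.

    Each pixel's linearized channel value is the von-Kries channel catch of
    its region's reflectance spectrum.  Returns the (linearized) image, an
    integer patch map with a ``labels`` ordering stored in the image
    metadata, and the ground-truth spectrum per label.
    """
    h, w = spec.size_px
    labels = [spec.background] + [name for name, _ in spec.rings]
    missing = [l for l in labels if l not in spec.region_archetypes]
    if missing:
        raise ValueError(f"scene labels without an archetype: {missing}")
    rng = np.random.default_rng(spec.seed)
    truth = {
        l: gen_reflectance(spec.region_archetypes[l], seed=int(rng.integers(2**31)))
        for l in labels
    }

    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.sqrt((yy - (h - 1) / 2.0) ** 2 + (xx - (w - 1) / 2.0) ** 2)
    short = min(h, w)
    patch_map = np.zeros((h, w), dtype=int)  # 0 = background
    # paint outermost first so inner rings overwrite
    for idx in range(len(spec.rings), 0, -1):
        _, frac = spec.rings[idx - 1]
        patch_map[rr <= frac * short] = idx

    chan_catch = {
        name: np.array(
            [quantum_catch(illuminant, truth[l], ConeClass(name, sens)) for l in labels]
        )
        for name, sens in channel_sensitivities.items()
    }
    texture = None
    if spec.texture_amp > 0:
        f = gaussian_filter(rng.standard_normal((h, w)), sigma=short / 16.0)
        f /= max(np.abs(f).max(), 1e-12)
        texture = 1.0 + spec.texture_amp * f

    channels = {}
    for name in channel_sensitivities:
        img = chan_catch[name][patch_map]
        if texture is not None:
            img = np.where(patch_map == 0, img * texture, img)
        if spec.noise_sd > 0:
            img = img + spec.noise_sd * rng.standard_normal((h, w))
        channels[name] = np.clip(img, 0.0, None)

    msi = MultispectralImage(
        channels,
        linearized=True,
        px_per_mm=spec.px_per_mm,
        scene_meta={"labels": labels, "seed": spec.seed},
    )
    return msi, patch_map, truth


def gen_texture_image(
    kind: str,
    size: tuple[int, int] = (128, 128),
    seed: int | None = None,
    level: float = 0.5,
    cycles: float = 8.0,
    theta_deg: float = 0.0,
    scale_px: float = 8.0,
) -> np.ndarray:
    """Deterministic texture fixtures: constant, grating, white noise, blobs.

    ``cycles`` is the grating frequency in cycles per image width along the
    grating direction; ``scale_px`` sets the blob-field correlation length.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    if kind == "constant":
        return np.full(size, level)
    if kind == "grating":
        if cycles > min(h, w) / 2:
            raise ValueError("grating frequency above Nyquist")
        yy, xx = np.mgrid[0:h, 0:w]
        th = np.deg2rad(theta_deg)
        phase = 2 * np.pi * cycles * (xx * np.cos(th) + yy * np.sin(th)) / w
        return level + 0.4 * np.sin(phase)
    if kind == "white_noise":
        return rng.standard_normal(size)
    if kind == "blob_field":
        f = gaussian_filter(rng.standard_normal(size), sigma=scale_px)
        return level + f / max(np.abs(f).max(), 1e-12) * 0.4
    raise ValueError(f"unknown texture kind {kind!r}")
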