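"""End-to-end orchestration: spectra path and image path.

The spectra path goes reflectance spectra -> quantum catches -> RNL
contrasts (+ bootstrap/PERMANOVA when replicate spectra exist).  The image
path goes linearized multispectral image -> cone-catch images (fitted
channel-to-cone mapping) -> acuity blur per viewing distance -> acuity-grid
sampling per ROI -> contrasts and statistics, plus texture analysis of the
luminance channel and false-color renders.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acuity import (
    DEFAULT_DISTANCES_M,
    ViewingGeometry,
    acuity_disk_px,
    acuity_grid_sample,
    blur_for_acuity,
)
from .calibration import CATCH_EPSILON, ConeMapping, MultispectralImage, apply_cone_mapping
from .contrast import classify_detectability, patch_pair_contrast
from .falsecolor import render_dichromat, render_luminance, render_tetrachromat, rescale_dichromat_contrast
from .spectra import Spectrum, d65_illuminant
from .stats import PatchSampleSet, bootstrap_contrast, permanova
from .texture import edge_fraction, granularity_spectrum, summarize
from .viewers import ViewerModel, catch_vector

__all__ = [
    "RunConfig",
    "run_spectra_pipeline",
    "run_image_pipeline",
    "CONTRAST_COLUMNS",
]

CONTRAST_COLUMNS = [
    "patch_p",
    "patch_q",
    "viewer",
    "distance_m",
    "dSc_mean",
    "dSc_sem",
    "dSc_ci_lo",
    "dSc_ci_hi",
    "dSc_detectability",
    "dSl_mean",
    "dSl_sem",
    "dSl_ci_lo",
    "dSl_ci_hi",
    "dSl_detectability",
    "pseudo_F",
    "p_value",
    "n_obs_p",
    "n_obs_q",
    "seed",
    "config_hash",
]


@dataclass(frozen=True)
class RunConfig:
    """Run parameters shared by the pipelines (provenance is hashed)."""

    distances_m: tuple[float, ...] = DEFAULT_DISTANCES_M
    n_boot: int = 1000
    n_perm: int = 1000
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.distances_m):
            raise ValueError("distances must be >= 0 (0 means no acuity blur)")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "distances_m": list(self.distances_m),
                "n_boot": self.n_boot,
                "n_perm": self.n_perm,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _pair_row(
    p: PatchSampleSet,
    q: PatchSampleSet,
    viewer: ViewerModel,
    distance_m: float,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> dict:
    """One contrast-table row for a patch pair (bootstrap + PERMANOVA)."""
    if p.n_obs >= 2 and q.n_obs >= 2:
        boot = bootstrap_contrast(p, q, n_boot=cfg.n_boot, seed=rng)
        f, pval = permanova([p.coords(), q.coords()], n_perm=cfg.n_perm, seed=rng)
        c, l = boot.color, boot.brightness
        row = {
            "dSc_mean": c.mean, "dSc_sem": c.sem,
            "dSc_ci_lo": c.ci95[0], "dSc_ci_hi": c.ci95[1],
            "dSl_mean": l.mean, "dSl_sem": l.sem,
            "dSl_ci_lo": l.ci95[0], "dSl_ci_hi": l.ci95[1],
            "pseudo_F": f, "p_value": pval,
        }
    else:  # single observation per patch: plain contrast, no inference
        from .viewers import QuantumCatchVector

        qp = QuantumCatchVector(viewer, p.Q[0], float(p.Q_lum[0]), p.patch_label)
        qq = QuantumCatchVector(viewer, q.Q[0], float(q.Q_lum[0]), q.patch_label)
        res = patch_pair_contrast(qp, qq)
        row = {
            "dSc_mean": res.delta_S_C, "dSc_sem": 0.0,
            "dSc_ci_lo": res.delta_S_C, "dSc_ci_hi": res.delta_S_C,
            "dSl_mean": res.delta_S_L, "dSl_sem": 0.0,
            "dSl_ci_lo": res.delta_S_L, "dSl_ci_hi": res.delta_S_L,
            "pseudo_F": float("nan"), "p_value": float("nan"),
        }
    row.update(
        patch_p=p.patch_label,
        patch_q=q.patch_label,
        viewer=viewer.name,
        distance_m=distance_m,
        dSc_detectability=classify_detectability(row["dSc_mean"]),
        dSl_detectability=classify_detectability(row["dSl_mean"]),
        n_obs_p=p.n_obs,
        n_obs_q=q.n_obs,
        seed=cfg.seed,
        config_hash=cfg.config_hash,
    )
    return row


def run_spectra_pipeline(
    patch_spectra: dict[str, list[Spectrum]],
    viewers: list[ViewerModel],
    illuminant: Spectrum | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Contrast table for every unordered patch pair and every viewer.

    ``patch_spectra`` maps patch label to replicate reflectance spectra
    (one spectrum is fine; statistics then degenerate to plain contrasts).
    """
    if len(patch_spectra) < 2:
        raise ValueError("need at least 2 patches")
    illuminant = illuminant if illuminant is not None else d65_illuminant()
    cfg = config or RunConfig(distances_m=(0.0,))
    rng = np.random.default_rng(cfg.seed)
    rows = []
    labels = list(patch_spectra)
    for viewer in viewers:
        sets = {}
        for label in labels:
            reps = patch_spectra[label]
            if isinstance(reps, Spectrum):
                reps = [reps]
            obs = [catch_vector(illuminant, s, viewer, label) for s in reps]
            sets[label] = PatchSampleSet.from_catch_vectors(label, obs)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                rows.append(_pair_row(sets[a], sets[b], viewer, float("nan"), cfg, rng))
    return pd.DataFrame(rows, columns=CONTRAST_COLUMNS)


def _sample_sets(
    catch_images: dict[str, np.ndarray],
    viewer: ViewerModel,
    rois: dict[str, np.ndarray],
    disk_px: int,
) -> dict[str, PatchSampleSet]:
    chrom_names = viewer.cone_names
    lum_img = catch_images[viewer.luminance_cone.name]
    out = {}
    for label, mask in rois.items():
        q_cols = [
            acuity_grid_sample(catch_images[n], mask, disk_px, fallback_center=True)
            for n in chrom_names
        ]
        q_lum = acuity_grid_sample(lum_img, mask, disk_px, fallback_center=True)
        Q = np.clip(np.stack(q_cols, axis=1), CATCH_EPSILON, None)
        out[label] = PatchSampleSet(label, viewer, Q, np.clip(q_lum, CATCH_EPSILON, None))
    return out


def run_image_pipeline(
    image: MultispectralImage,
    rois: dict[str, np.ndarray],
    viewers: list[ViewerModel],
    mappings: dict[str, ConeMapping],
    config: RunConfig | None = None,
    no_blur_disk_px: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Image-path analysis per viewer and viewing distance.

    Returns (contrast table, texture table, false-color renders keyed by
    (viewer, distance)).  A distance of 0 means no acuity blur; independent
    samples are then spaced ``no_blur_disk_px`` apart.
    """
    if not image.linearized:
        raise ValueError("image must be linearized")
    cfg = config or RunConfig()
    rng = np.random.default_rng(cfg.seed)
    contrast_rows, texture_rows, renders = [], [], {}
    labels = list(rois)
    for viewer in viewers:
        mapping = mappings[viewer.name]
        catch_images = apply_cone_mapping(image, mapping)
        for dist in cfg.distances_m:
            if dist > 0:
                geom = ViewingGeometry(dist, image.px_per_mm)
                blurred = {
                    n: blur_for_acuity(img, viewer, geom)
                    for n, img in catch_images.items()
                }
                disk = acuity_disk_px(viewer, geom)
            else:
                blurred = {n: img.copy() for n, img in catch_images.items()}
                disk = no_blur_disk_px
            sets = _sample_sets(blurred, viewer, rois, disk)
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    contrast_rows.append(
                        _pair_row(sets[a], sets[b], viewer, dist, cfg, rng)
                    )
            # texture on the sqrt-tone-mapped luminance channel
            lum = render_luminance(np.clip(blurred[viewer.luminance_cone.name], 0, 1))
            n_bands = min(8, int(np.log2(min(lum.shape))))
            for label in labels:
                spec = granularity_spectrum(lum, rois[label], n_bands=n_bands)
                stats = summarize(spec)
                texture_rows.append(
                    {
                        "roi": label,
                        "viewer": viewer.name,
                        "distance_m": dist,
                        "total_energy": stats.total_energy,
                        "proportion_energy": stats.proportion_energy,
                        "peak_filter": stats.peak_filter,
                        "edge_fraction": edge_fraction(lum, rois[label]),
                        "seed": cfg.seed,
                        "config_hash": cfg.config_hash,
                    }
                )
            renders[(viewer.name, dist)] = _render(viewer, blurred)
    return (
        pd.DataFrame(contrast_rows, columns=CONTRAST_COLUMNS),
        pd.DataFrame(texture_rows),
        renders,
    )


def _render(viewer: ViewerModel, catch_images: dict[str, np.ndarray]) -> dict:
    clipped = {n: np.clip(img, 0.0, 1.0) for n, img in catch_images.items()}
    names = viewer.cone_names
    out = {"luminance": render_luminance(clipped[viewer.luminance_cone.name])}
    if viewer.n_chromatic == 4:
        rgb, vs = render_tetrachromat(
            clipped[names[3]], clipped[names[2]], clipped[names[1]], clipped[names[0]]
        )
        out["rgb"] = rgb
        out["vs_gray"] = vs
    else:
        rgb = render_dichromat(clipped[names[0]], clipped[names[1]])
        out["rgb"] = rgb
        out["rgb_rescaled"] = rescale_dichromat_contrast(rgb)
    return out
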