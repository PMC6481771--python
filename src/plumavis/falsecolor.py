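"""False-color rendering of cone-catch images for human viewing.

Catch images are tone-mapped with a square root (an approximation to human
brightness perception) and packed into displayable images: tetrachromat
vision as an RGB image from the LWS/MWS/SWS catches plus a separate VS/UVS
grayscale; dichromat vision as a blue-yellow image with B = sqrt(Q_S) and
R = G = sqrt(Q_L) (so the red-green opponency channel is identically zero).

Because a human observer has lower Weber fractions (better contrast
discrimination) than a dichromatic carnivoran, dichromat renders can be
contrast-rescaled in CIE L*a*b*: the L* channel is compressed about its
image mean by the ratio of human to dog luminance Weber fractions, and the
blue-yellow b channel is multiplied by the ratio of human to dog chromatic
Weber fractions.  These renders are a relative guide to appearance, not a
quantitative detectability measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import lab2rgb, rgb2lab

__all__ = [
    "RescaleParams",
    "render_tetrachromat",
    "render_dichromat",
    "render_luminance",
    "rescale_dichromat_contrast",
]


@dataclass(frozen=True)
class RescaleParams:
    """Weber fractions used to match dichromat contrast to human perception.

    Defaults: human luminance 0.14 vs dog 0.22; human chromatic 0.06 vs dog
    0.22.
    """

    w_Lh: float = 0.14
    w_Ld: float = 0.22
    w_Ch: float = 0.06
    w_Cd: float = 0.22

    def __post_init__(self) -> None:
        if min(self.w_Lh, self.w_Ld, self.w_Ch, self.w_Cd) <= 0:
            raise ValueError("Weber fractions must be positive")


def _sqrt_tone(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("quantum catches must be non-negative for rendering")
    return np.sqrt(q)


def render_tetrachromat(
    lws: np.ndarray, mws: np.ndarray, sws: np.ndarray, vs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(RGB from sqrt(LWS/MWS/SWS), grayscale from sqrt(VS or UVS))."""
    rgb = np.stack([_sqrt_tone(lws), _sqrt_tone(mws), _sqrt_tone(sws)], axis=-1)
    return rgb, _sqrt_tone(vs)


def render_dichromat(q_s: np.ndarray, q_l: np.ndarray) -> np.ndarray:
    """Blue-yellow dichromat render: B = sqrt(Q_S), R = G = sqrt(Q_L)."""
    yellow = _sqrt_tone(q_l)
    return np.stack([yellow, yellow, _sqrt_tone(q_s)], axis=-1)


def render_luminance(q_lum: np.ndarray) -> np.ndarray:
    """Luminance-only grayscale render, sqrt tone-mapped."""
    return _sqrt_tone(q_lum)


def rescale_dichromat_contrast(
    rgb: np.ndarray, params: RescaleParams = RescaleParams()
) -> np.ndarray:
    """Reduce a dichromat render's contrast to the dichromat's Weber scale.

    In L*a*b* (D65, 2 degree observer): L* is compressed about its image
    mean by w_Lh/w_Ld (mean preserved); the b (blue-yellow) channel is
    multiplied by w_Ch/w_Cd; a is untouched.  The result is converted back
    to sRGB and clipped to gamut.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    lab = rgb2lab(np.clip(rgb, 0.0, 1.0))
    L = lab[..., 0]
    Lm = L.mean()
    lab[..., 0] = params.w_Lh / params.w_Ld * (L - Lm) + Lm
    lab[..., 2] *= params.w_Ch / params.w_Cd
    out = lab2rgb(lab)
    return np.clip(out, 0.0, 1.0)
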