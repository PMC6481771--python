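"""Receptor-noise-limited (RNL) color and brightness contrast in JND.

The RNL model measures the discriminability of two surface patches as a
noise-weighted distance between their log receptor signals.  With per-cone
log-signal differences Delta_r = ln Q_rp - ln Q_rq and noises e_r, the
chromatic contrast for n receptor classes is

    dS_C^2 = sum_{i<j} (prod_{k not in {i,j}} e_k)^2 (Delta_i - Delta_j)^2
             ---------------------------------------------------------------
                      sum_i (prod_{k != i} e_k)^2

which for a dichromat (n = 2) reduces to the familiar closed form
|Delta_L - Delta_S| / sqrt(e_L^2 + e_S^2), and for a tetrachromat sums over
all six opponent pairs of the four single cones.  Brightness contrast is the
Weber-scaled log-luminance difference dS_L = (ln Q_Lp - ln Q_Lq) / w_f.

Contrasts are in just-noticeable-difference (JND) units: 1 JND is the ideal
discrimination threshold; 1-3 JND is treated as weakly detectable.  Natural
logarithms are used throughout.  Only the bright-illumination regime is
modeled, where receptor noise is catch-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .viewers import QuantumCatchVector, receptor_noise

__all__ = [
    "ContrastResult",
    "log_receptor_signal",
    "chromatic_contrast",
    "brightness_contrast",
    "classify_detectability",
    "patch_pair_contrast",
]

#: JND detectability band edges: <=1 below threshold, (1, 3] weakly detectable.
DETECTION_THRESHOLD_JND = 1.0
WEAK_DETECTION_CEILING_JND = 3.0


@dataclass(frozen=True)
class ContrastResult:
    """Chromatic and brightness contrast (JND) for one patch pair."""

    patch_pair: tuple[str, str]
    viewer_name: str
    delta_S_C: float
    delta_S_L: float
    detectability_color: str
    detectability_brightness: str


def log_receptor_signal(qp: QuantumCatchVector, qq: QuantumCatchVector) -> np.ndarray:
    """Per-cone log-signal differences Delta_r = ln Q_rp - ln Q_rq."""
    if qp.viewer is not qq.viewer and qp.viewer != qq.viewer:
        raise ValueError("both catch vectors must come from the same viewer")
    return np.log(qp.Q) - np.log(qq.Q)


def chromatic_contrast(delta: np.ndarray, noise: np.ndarray) -> float:
    """General n-receptor RNL chromatic distance in JND.

    ``delta`` are per-cone log-signal differences, ``noise`` the per-cone
    Weber noises e_r.  The distance is invariant under adding a constant to
    all deltas (illumination invariance) and symmetric in the two patches.
    """
    delta = np.asarray(delta, dtype=float)
    e = np.asarray(noise, dtype=float)
    n = delta.size
    if n < 2 or e.size != n:
        raise ValueError("need >= 2 cones and matching noise vector")
    if np.any(e <= 0):
        raise ValueError("receptor noises must be positive")
    # products of all noises but one / but two, via the full product
    log_e = np.log(e)
    log_all = log_e.sum()
    # denominator: sum_i (prod_{k != i} e_k)^2
    denom = np.exp(2.0 * (log_all - log_e)).sum()
    num = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            w = np.exp(2.0 * (log_all - log_e[i] - log_e[j]))
            num += w * (delta[i] - delta[j]) ** 2
    return float(np.sqrt(num / denom))


def brightness_contrast(q_lp: float, q_lq: float, w_f_L: float, signed: bool = False) -> float:
    """Weber brightness contrast dS_L = (ln Q_Lp - ln Q_Lq) / w_f (JND).

    Absolute value by default; pass ``signed=True`` to keep the direction.
    """
    if q_lp <= 0 or q_lq <= 0 or w_f_L <= 0:
        raise ValueError("luminance catches and Weber fraction must be positive")
    d = (np.log(q_lp) - np.log(q_lq)) / w_f_L
    return float(d if signed else abs(d))


def classify_detectability(jnd: float) -> str:
    """Band a JND value: below_threshold (<=1), weakly_detectable (1-3], detectable (>3)."""
    if jnd < 0:
        raise ValueError("JND must be non-negative")
    if jnd <= DETECTION_THRESHOLD_JND:
        return "below_threshold"
    if jnd <= WEAK_DETECTION_CEILING_JND:
        return "weakly_detectable"
    return "detectable"


def patch_pair_contrast(qp: QuantumCatchVector, qq: QuantumCatchVector) -> ContrastResult:
    """Full RNL contrast result for one patch pair seen by one viewer."""
    viewer = qp.viewer
    delta = log_receptor_signal(qp, qq)
    e = receptor_noise(viewer)
    dsc = chromatic_contrast(delta, e)
    dsl = brightness_contrast(qp.Q_lum, qq.Q_lum, viewer.luminance_weber)
    return ContrastResult(
        patch_pair=(qp.patch_label, qq.patch_label),
        viewer_name=viewer.name,
        delta_S_C=dsc,
        delta_S_L=dsl,
        detectability_color=classify_detectability(dsc),
        detectability_brightness=classify_detectability(dsl),
    )
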