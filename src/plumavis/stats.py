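"""Bootstrap effect-size estimation and permutation significance tests.

Two-step inference for patch-pair visual contrasts: (1) a permutational
multivariate analysis of variance (PERMANOVA) on colorspace coordinates
asks whether two patches differ statistically in the viewer's colorspace;
(2) a bootstrap over the acuity-grid samples estimates the mean JND contrast
and its uncertainty (the perceptual effect size).  A difference can be
statistically significant yet below 1 JND — real but imperceptible — which
is why both are reported.

All confidence intervals follow the convention 95% CI = mean +/- 2 s.e.m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .contrast import brightness_contrast
from .viewers import QuantumCatchVector, ViewerModel, receptor_noise

__all__ = [
    "PatchSampleSet",
    "ContrastSummary",
    "BootstrapContrast",
    "chromatic_contrast_batch",
    "bootstrap_contrast",
    "permanova",
    "grand_mean",
]


@dataclass(frozen=True)
class PatchSampleSet:
    """Repeated catch observations (acuity-grid samples) for one patch."""

    patch_label: str
    viewer: ViewerModel
    Q: np.ndarray  # (n_obs, n_chromatic)
    Q_lum: np.ndarray  # (n_obs,)

    def __post_init__(self) -> None:
        q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        ql = np.atleast_1d(np.asarray(self.Q_lum, dtype=float))
        if q.shape[0] != ql.shape[0]:
            raise ValueError("chromatic and luminance observation counts differ")
        if q.shape[1] != self.viewer.n_chromatic:
            raise ValueError("observation width must match viewer cone count")
        if np.any(q <= 0) or np.any(ql <= 0):
            raise ValueError("quantum catches must be strictly positive")
        object.__setattr__(self, "Q", q)
        object.__setattr__(self, "Q_lum", ql)

    @classmethod
    def from_catch_vectors(
        cls, label: str, observations: list[QuantumCatchVector]
    ) -> "PatchSampleSet":
        if not observations:
            raise ValueError("need at least one observation")
        viewer = observations[0].viewer
        return cls(
            label,
            viewer,
            np.stack([o.Q for o in observations]),
            np.array([o.Q_lum for o in observations]),
        )

    @property
    def n_obs(self) -> int:
        return self.Q.shape[0]

    def coords(self) -> np.ndarray:
        """Simplex colorspace coordinates per observation (rows sum to 1)."""
        return self.Q / self.Q.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class ContrastSummary:
    """Bootstrap mean, s.e.m. and 95% CI (= +/- 2 s.e.m.) for one channel."""

    mean: float
    sem: float
    ci95: tuple[float, float]
    n_boot: int
    p_value: float = float("nan")
    pseudo_F: float = float("nan")


@dataclass(frozen=True)
class BootstrapContrast:
    """Bootstrap summaries for the chromatic and brightness channels."""

    color: ContrastSummary
    brightness: ContrastSummary


def chromatic_contrast_batch(deltas: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """Vectorized RNL chromatic distance for (m, n_cones) delta rows."""
    d = np.atleast_2d(np.asarray(deltas, dtype=float))
    e = np.asarray(noise, dtype=float)
    n = e.size
    log_e = np.log(e)
    log_all = log_e.sum()
    denom = np.exp(2.0 * (log_all - log_e)).sum()
    num = np.zeros(d.shape[0])
    for i in range(n):
        for j in range(i + 1, n):
            w = np.exp(2.0 * (log_all - log_e[i] - log_e[j]))
            num += w * (d[:, i] - d[:, j]) ** 2
    return np.sqrt(num / denom)


def _pair_contrasts(
    p: PatchSampleSet, q: PatchSampleSet, idx_p: np.ndarray, idx_q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    viewer = p.viewer
    e = receptor_noise(viewer)
    deltas = np.log(p.Q[idx_p]) - np.log(q.Q[idx_q])
    dsc = chromatic_contrast_batch(deltas, e)
    dsl = np.abs(np.log(p.Q_lum[idx_p]) - np.log(q.Q_lum[idx_q])) / viewer.luminance_weber
    return dsc, dsl


def bootstrap_contrast(
    p: PatchSampleSet,
    q: PatchSampleSet,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> BootstrapContrast:
    """Bootstrap the mean chromatic and brightness contrast of a patch pair.

    Each of ``n_boot`` resamples draws observation pairs with replacement
    from the two sample sets and records the mean dS_C and dS_L; the
    reported mean and s.e.m. are taken over resample means, with
    CI = mean +/- 2 s.e.m.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if p.viewer != q.viewer:
        raise ValueError("both patches must be observed by the same viewer")
    rng = np.random.default_rng(seed)
    n_pairs = max(p.n_obs, q.n_obs)
    means_c = np.empty(n_boot)
    means_l = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.integers(0, p.n_obs, size=n_pairs)
        iq = rng.integers(0, q.n_obs, size=n_pairs)
        dsc, dsl = _pair_contrasts(p, q, ip, iq)
        means_c[b] = dsc.mean()
        means_l[b] = dsl.mean()

    def summarize(m: np.ndarray) -> ContrastSummary:
        mean = float(m.mean())
        sem = float(m.std(ddof=1))  # SD of the bootstrap distribution = s.e.m.
        return ContrastSummary(mean, sem, (mean - 2 * sem, mean + 2 * sem), n_boot)

    return BootstrapContrast(summarize(means_c), summarize(means_l))


def _ss_within(D2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = D2[np.ix_(idx, idx)]
        ss += sub.sum() / (2.0 * idx.size)
    return ss


def permanova(
    group_coords: list[np.ndarray],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    rank_transform: bool = False,
) -> tuple[float, float]:
    """One-way PERMANOVA on Euclidean distances among colorspace coordinates.

    pseudo-F = (SS_between/(k-1)) / (SS_within/(N-k)), with the null built
    by permuting group labels; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)
    (add-one convention, so p is never exactly zero).  ``rank_transform``
    replaces squared distances by their ranks, an approximation for heavily
    heteroscedastic data.
    """
    if len(group_coords) < 2:
        raise ValueError("need >= 2 groups")
    coords = [np.atleast_2d(np.asarray(g, dtype=float)) for g in group_coords]
    if any(g.shape[0] < 2 for g in coords):
        raise ValueError("every group needs >= 2 observations")
    X = np.vstack(coords)
    labels = np.concatenate(
        [np.full(g.shape[0], i) for i, g in enumerate(coords)]
    )
    N = X.shape[0]
    k = len(coords)
    diff = X[:, None, :] - X[None, :, :]
    D2 = np.einsum("ijk,ijk->ij", diff, diff)
    if rank_transform:
        iu = np.triu_indices(N, 1)
        r = rankdata(D2[iu])
        R = np.zeros_like(D2)
        R[iu] = r
        D2 = R + R.T
    ss_total = D2.sum() / (2.0 * N)
    groups = np.arange(k)

    def pseudo_f(lab: np.ndarray) -> float:
        ssw = _ss_within(D2, lab, groups)
        ssb = ss_total - ssw
        if ssw <= 0:
            return np.inf
        return (ssb / (k - 1)) / (ssw / (N - k))

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(labels)) >= f_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return float(f_obs), float(p)


def grand_mean(summaries: list[ContrastSummary]) -> ContrastSummary:
    """Average replicate summaries; s.e.m. is taken across replicate means."""
    if not summaries:
        raise ValueError("need at least one replicate summary")
    means = np.array([s.mean for s in summaries])
    mean = float(means.mean())
    sem = float(means.std(ddof=1) / np.sqrt(means.size)) if means.size > 1 else 0.0
    return ContrastSummary(
        mean, sem, (mean - 2 * sem, mean + 2 * sem), n_boot=summaries[0].n_boot
    )
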