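"""Camera linearization (S-log law) and channel-to-cone-catch mapping.

A consumer camera's pixel value V is related to scene reflectance R by an
S-log law fitted from a multi-step grayscale diffuse reflectance standard:

    R(V) = A * exp(-V / T_o) + C

Linearized multispectral images (a UV-filter blue channel plus visible R, G,
B channels) are then mapped to the viewer's cone quantum catches with a
linear model including all pairwise (2-way) interaction terms, trained on a
library of natural-like reflectance spectra: for each training spectrum the
channel catches (von-Kries integral against each channel's spectral
sensitivity) and the cone catches (same against each cone sensitivity) are
computed, and each cone catch is regressed on the channel catches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import PolynomialFeatures

from .spectra import Spectrum
from .viewers import ConeClass, ViewerModel, quantum_catch

__all__ = [
    "SlogParams",
    "GrayscaleStandard",
    "MultispectralImage",
    "ConeMapping",
    "fit_slog",
    "invert_slog",
    "apply_slog",
    "linearize",
    "fit_cone_mapping",
    "apply_cone_mapping",
    "validate_colorspace",
]

#: Floor applied to mapped catches before any log operation downstream.
CATCH_EPSILON = 1e-6

#: Canonical channel order for the two-exposure multispectral stack.
CHANNELS = ("uv_b", "vis_r", "vis_g", "vis_b")


@dataclass(frozen=True)
class SlogParams:
    """Fitted S-log parameters for one camera channel."""

    A: float
    T_o: float
    C: float
    fit_quality: float = float("nan")  # adjusted R^2
    channel: str = ""

    def __post_init__(self) -> None:
        if self.T_o == 0:
            raise ValueError("T_o must be nonzero")

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "T_o": self.T_o,
            "C": self.C,
            "fit_quality": self.fit_quality,
            "channel": self.channel,
        }


@dataclass(frozen=True)
class GrayscaleStandard:
    """Known step reflectances and the mean pixel value observed per channel.

    ``reflectances`` has one entry per grayscale step (fractions in (0, 1]);
    ``pixel_values`` maps channel name to the per-step mean pixel values.
    """

    reflectances: np.ndarray
    pixel_values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectances, dtype=float)
        if r.size < 4:
            raise ValueError("need >= 4 grayscale steps to fit 3 parameters")
        if np.any(r <= 0) or np.any(r > 1.0):
            raise ValueError("step reflectances must lie in (0, 1]")
        object.__setattr__(self, "reflectances", r)
        pv = {k: np.asarray(v, dtype=float) for k, v in self.pixel_values.items()}
        for k, v in pv.items():
            if v.shape != r.shape:
                raise ValueError(f"channel {k!r}: pixel values must match step count")
        object.__setattr__(self, "pixel_values", pv)


@dataclass
class MultispectralImage:
    """Aligned channel stack from the UV and visible exposures.

    ``channels`` maps channel name to a 2-D float array, all on one pixel
    grid.  ``linearized`` is False for raw pixel values and True once the
    S-log law has been applied (values then in [0, 1]).  ``px_per_mm`` is
    the object-plane spatial calibration; ``scene_meta`` carries free-form
    acquisition metadata (illumination angles, distance, ...).
    """

    channels: dict[str, np.ndarray]
    linearized: bool = False
    px_per_mm: float = 1.0
    scene_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one pixel grid")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def apply_slog(params: SlogParams, V: np.ndarray) -> np.ndarray:
    """Reflectance from pixel value: R(V) = A exp(-V/T_o) + C."""
    return params.A * np.exp(-np.asarray(V, dtype=float) / params.T_o) + params.C


def invert_slog(params: SlogParams, R: np.ndarray) -> np.ndarray:
    """Pixel value from reflectance: V = -T_o ln((R - C)/A)."""
    arg = (np.asarray(R, dtype=float) - params.C) / params.A
    if np.any(arg <= 0):
        raise ValueError("reflectance outside the invertible range of the S-log law")
    return -params.T_o * np.log(arg)


def fit_slog(standard: GrayscaleStandard, channel: str) -> SlogParams:
    """Nonlinear least-squares fit of the S-log law for one channel.

    Raises a fit error when the design is degenerate (constant reflectance
    or constant pixel value leaves A/T_o unidentifiable).
    """
    if channel not in standard.pixel_values:
        raise KeyError(f"channel {channel!r} not present in the grayscale standard")
    V = standard.pixel_values[channel]
    R = standard.reflectances
    if np.ptp(R) < 1e-12 or np.ptp(V) < 1e-12:
        raise RuntimeError("degenerate grayscale design: no variation to fit")

    order = np.argsort(V)
    Vs, Rs = V[order], R[order]
    C0 = Rs[-1] + 0.05 * (Rs[-1] - Rs[0])
    A0 = Rs[0] - C0
    T0 = max(np.ptp(V) / 2.0, 1e-3)

    def model(v, A, T_o, C):
        return A * np.exp(-v / T_o) + C

    try:
        popt, _ = curve_fit(model, V, R, p0=(A0, T0, C0), maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"S-log fit did not converge for {channel!r}: {err}") from err

    resid = R - model(V, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(((R - R.mean()) ** 2).sum())
    n, p = R.size, 3
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else r2
    return SlogParams(float(popt[0]), float(popt[1]), float(popt[2]), adj, channel)


def linearize(
    image: MultispectralImage, params: dict[str, SlogParams]
) -> MultispectralImage:
    """Apply per-channel S-log linearization; clip to [0, 1], set the flag."""
    missing = set(image.channels) - set(params)
    if missing:
        raise KeyError(f"missing S-log parameters for channels: {sorted(missing)}")
    out = {
        name: np.clip(apply_slog(params[name], arr), 0.0, 1.0)
        for name, arr in image.channels.items()
    }
    return replace(image, channels=out, linearized=True)


# -- cone mapping ------------------------------------------------------------

def _interaction_features(X: np.ndarray) -> tuple[np.ndarray, PolynomialFeatures]:
    pf = PolynomialFeatures(degree=2, interaction_only=True, include_bias=False)
    return pf.fit_transform(X), pf


@dataclass(frozen=True)
class ConeMapping:
    """Fitted linear 2-way-interaction map from channel catches to cone catches."""

    channel_names: tuple[str, ...]
    cone_names: tuple[str, ...]
    coefficients: np.ndarray  # (n_cones, n_features)
    intercepts: np.ndarray  # (n_cones,)
    fit_quality: np.ndarray  # per-cone R^2
    feature_names: tuple[str, ...]

    def predict(self, channel_catches: np.ndarray) -> np.ndarray:
        """Map (n_samples, n_channels) channel catches to (n_samples, n_cones)."""
        X = np.asarray(channel_catches, dtype=float)
        feats, _ = _interaction_features(X)
        return feats @ self.coefficients.T + self.intercepts

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "channel_names": list(self.channel_names),
                    "cone_names": list(self.cone_names),
                    "coefficients": self.coefficients.tolist(),
                    "intercepts": self.intercepts.tolist(),
                    "fit_quality": self.fit_quality.tolist(),
                    "feature_names": list(self.feature_names),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ConeMapping":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tuple(d["channel_names"]),
            tuple(d["cone_names"]),
            np.asarray(d["coefficients"], float),
            np.asarray(d["intercepts"], float),
            np.asarray(d["fit_quality"], float),
            tuple(d["feature_names"]),
        )


def channel_catches(
    illuminant: Spectrum,
    reflectance: Spectrum,
    channel_sensitivities: dict[str, Spectrum],
) -> np.ndarray:
    """Von-Kries channel catches of one reflectance for each camera channel."""
    return np.array(
        [
            quantum_catch(illuminant, reflectance, ConeClass(name, sens))
            for name, sens in channel_sensitivities.items()
        ]
    )


def fit_cone_mapping(
    channel_sensitivities: dict[str, Spectrum],
    viewer: ViewerModel,
    training_spectra: list[Spectrum],
    illuminant: Spectrum,
    include_luminance: bool = True,
) -> ConeMapping:
    """Fit the channel-to-cone mapping on a training reflectance library.

    Requires >= 50 training spectra spanning the gamut.  Reports per-cone
    R^2 on the training set; the luminance cone is appended after the
    chromatic cones when ``include_luminance``.
    """
    if len(training_spectra) < 50:
        raise ValueError("need >= 50 training spectra spanning the gamut")
    cones = list(viewer.chromatic_cones)
    if include_luminance:
        cones.append(viewer.luminance_cone)

    X = np.stack(
        [channel_catches(illuminant, r, channel_sensitivities) for r in training_spectra]
    )
    Y = np.stack(
        [
            [quantum_catch(illuminant, r, c) for c in cones]
            for r in training_spectra
        ]
    )
    feats, pf = _interaction_features(X)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(feats)), feats])) < feats.shape[1] + 1:
        raise RuntimeError("rank-deficient design: training spectra do not span the gamut")
    reg = LinearRegression().fit(feats, Y)
    pred = reg.predict(feats)
    ss_res = ((Y - pred) ** 2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    r2 = 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, np.nan)
    return ConeMapping(
        tuple(channel_sensitivities),
        tuple(c.name for c in cones),
        np.atleast_2d(reg.coef_),
        np.atleast_1d(reg.intercept_),
        r2,
        tuple(pf.get_feature_names_out([f"x{i}" for i in range(X.shape[1])])),
    )


def apply_cone_mapping(
    image: MultispectralImage, mapping: ConeMapping
) -> dict[str, np.ndarray]:
    """Per-pixel cone-catch images from a linearized multispectral image.

    Mapped catches are floored at a small positive epsilon so that log-based
    contrast operations downstream never fail.
    """
    if not image.linearized:
        raise ValueError("image must be linearized before cone mapping")
    missing = set(mapping.channel_names) - set(image.channels)
    if missing:
        raise KeyError(f"image lacks channels required by the mapping: {sorted(missing)}")
    h, w = image.shape
    X = np.stack(
        [image.channels[name].ravel() for name in mapping.channel_names], axis=1
    )
    pred = mapping.predict(X)
    pred = np.clip(pred, CATCH_EPSILON, None)
    return {
        name: pred[:, i].reshape(h, w) for i, name in enumerate(mapping.cone_names)
    }


def validate_colorspace(sw_image: np.ndarray, sw_spectra: np.ndarray):
    """OLS regression of image-path sw on spectra-path sw for paired patches.

    Returns (slope, intercept, adjusted R^2).  Used to validate the camera
    pipeline: a calibrated system gives unit slope and zero intercept.
    """
    y = np.asarray(sw_image, dtype=float)
    x = np.asarray(sw_spectra, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need >= 3 paired patches")
    if np.ptp(x) < 1e-12:
        raise ValueError("spectra-path coordinates have zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.params[0]), float(res.rsquared_adj)
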