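"""The 18 per-channel statistical and frequency-domain features.

Each sensor channel of a frame is summarized by 18 scalars (15 statistical,
3 frequency-related), concatenated channel-major into an ``18 * S`` vector,
then min-max normalized per dimension with constants fit on the training set.

Conventions for quantities the bare feature names leave open:

* zero-crossings are counted after mean-centering — raw accelerometer
  channels carry a gravity offset that would make the uncentered count
  degenerate;
* moments use population normalization; skewness ``g1 = m3 / m2^1.5`` and
  *excess* kurtosis ``m4 / m2^2 - 3``, both 0 for a constant series;
* auto-correlation is the lag-1 mean-centered coefficient, 0 when the
  variance is 0;
* "first/second-order mean" is the mean of first/second discrete
  differences, and its "norm" the absolute value of that mean;
* spectral energy/entropy are computed on the non-DC half-spectrum (the DC
  bin only duplicates the mean); entropy is Shannon entropy in bits of the
  normalized power spectrum, with 0 log 0 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, SpecError
from .io import FeatureMatrix
from .segment import FrameSet

FEATURE_NAMES: tuple[str, ...] = (
    "max", "min", "mean", "sd", "zero_crossings",
    "p20", "p50", "p80", "iqr",
    "skewness", "kurtosis", "autocorr",
    "diff1_mean", "diff1_mean_abs", "diff2_mean", "diff2_mean_abs",
    "spectral_energy", "spectral_entropy",
)

N_FEATURES = len(FEATURE_NAMES)     # 18


def compute_channel_features(x: np.ndarray) -> np.ndarray:
    """Compute the 18 features of one channel's length-T series.

    Returns them in the order of :data:`FEATURE_NAMES`.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise InputError("need a 1-D series of length >= 4")
    if not np.all(np.isfinite(x)):
        raise InputError("series contains non-finite values")

    mean = x.mean()
    centered = x - mean
    m2 = np.mean(centered ** 2)
    sd = np.sqrt(m2)
    # a constant series leaves O(eps) residuals after mean subtraction;
    # ratio- and sign-based features would then quantify roundoff noise
    degenerate = sd <= 1e-13 * np.max(np.abs(x), initial=0.0)

    zc = 0 if degenerate else int(np.sum(centered[:-1] * centered[1:] < 0))

    p20, p25, p50, p75, p80 = np.percentile(x, [20, 25, 50, 75, 80])

    if not degenerate:
        skew = np.mean(centered ** 3) / m2 ** 1.5
        kurt = np.mean(centered ** 4) / m2 ** 2 - 3.0
        autocorr = float(np.sum(centered[:-1] * centered[1:]) / np.sum(centered ** 2))
    else:
        skew = kurt = autocorr = 0.0

    d1 = np.diff(x)
    d2 = np.diff(x, n=2)
    d1_mean = d1.mean()
    d2_mean = d2.mean()

    if not degenerate:    # constant series: non-DC power is 0 by Parseval
        spectrum = np.fft.rfft(x)[1:]      # non-DC bins
        power = np.abs(spectrum) ** 2
        energy = power.mean() if power.size else 0.0
        total = power.sum()
        if total > 0:
            p = power / total
            nz = p[p > 0]
            entropy = float(-(nz * np.log2(nz)).sum())
        else:
            entropy = 0.0
    else:
        energy = entropy = 0.0

    return np.array([
        x.max(), x.min(), mean, sd, zc,
        p20, p50, p80, p75 - p25,
        skew, kurt, autocorr,
        d1_mean, abs(d1_mean), d2_mean, abs(d2_mean),
        energy, entropy,
    ])


def compute_frame_features(frame_matrix: np.ndarray) -> np.ndarray:
    """Channel-major concatenation of per-channel features: length ``18 * S``."""
    frame_matrix = np.asarray(frame_matrix, dtype=float)
    if frame_matrix.ndim != 2:
        raise InputError("frame must be a T x S matrix")
    return np.concatenate(
        [compute_channel_features(frame_matrix[:, s])
         for s in range(frame_matrix.shape[1])]
    )


def feature_names_for(channel_names: list[str] | int) -> list[str]:
    if isinstance(channel_names, int):
        channel_names = [f"ch{i}" for i in range(channel_names)]
    return [f"{ch}:{f}" for ch in channel_names for f in FEATURE_NAMES]


def compute_features(frameset: FrameSet) -> FeatureMatrix:
    """Hand-crafted feature matrix for a whole frame set (un-normalized)."""
    X = np.stack([compute_frame_features(frameset.data[i])
                  for i in range(len(frameset))]) if len(frameset) else \
        np.empty((0, N_FEATURES * frameset.S))
    return FeatureMatrix(X=X, labels=frameset.labels.copy(),
                         feature_names=feature_names_for(frameset.S))


@dataclass
class NormalizationConstants:
    """Per-dimension min/max fit on training features."""

    min: np.ndarray
    max: np.ndarray

    def __post_init__(self) -> None:
        self.min = np.asarray(self.min, dtype=float)
        self.max = np.asarray(self.max, dtype=float)
        if np.any(self.min > self.max):
            raise SpecError("min must be <= max elementwise")


def fit_minmax(training: FeatureMatrix) -> NormalizationConstants:
    """Training-set min/max per feature dimension."""
    if training.n_frames < 1:
        raise InputError("cannot fit normalization constants on an empty set")
    return NormalizationConstants(min=training.X.min(axis=0),
                                  max=training.X.max(axis=0))


def apply_minmax(features: FeatureMatrix,
                 constants: NormalizationConstants) -> FeatureMatrix:
    """Project each dimension with ``(x - min) / (max - min)``.

    Training features land in [0, 1]; test features reuse the training
    constants and are deliberately *not* clipped.  A degenerate dimension
    (min == max on the training set) maps to 0.
    """
    span = constants.max - constants.min
    safe = np.where(span > 0, span, 1.0)
    X = (features.X - constants.min) / safe
    X[:, span == 0] = 0.0
    return FeatureMatrix(X=X, labels=features.labels.copy(),
                         feature_names=features.feature_names)
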