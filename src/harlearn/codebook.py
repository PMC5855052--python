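"""Bag-of-codewords features for sensor time series.

Codebook construction clusters subsequences (sliding windows of length ``w``
sampled with stride ``l``) with restarted k-means under Euclidean distance:
the clustering runs 10 times from random initializations and the restart
with the minimal *sum of Euclidean distances* between subsequences and their
assigned centers is kept.  Codeword assignment then encodes a series as a
histogram over the ``N`` codewords, either *hard* (each subsequence counts
for its nearest codeword) or *soft* (each subsequence spreads a unit of mass
across codewords through a Gaussian kernel of its distances — kernel density
estimation — so the smoothed frequency of codeword ``c_n`` is the average
over subsequences of ``K_sigma(D(x_s, c_n)) / sum_n' K_sigma(D(x_s, c_n'))``
with ``K_sigma(d) = exp(-d^2 / (2 sigma^2))``).

Channels are handled in one of two modes: ``per_channel`` builds one codebook
per sensor channel and concatenates the ``S`` histograms (early fusion,
``S * N`` dimensions); ``multivariate`` clusters time-major flattenings of
``w x S`` blocks into a single codebook (``N`` dimensions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import softmax

from .errors import InputError, SpecError
from .io import FeatureMatrix
from .segment import FrameSet


@dataclass
class CodebookConfig:
    width: int = 24                  # subsequence length w (samples)
    stride: int = 1                  # sampling stride l (samples)
    n_codewords: int = 128           # N
    sigma: float = 256.0             # soft-assignment smoothing (distance units)
    mode: str = "per_channel"        # {"per_channel", "multivariate"}
    restarts: int = 10
    max_iter: int = 300
    max_subsequences: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 2:
            raise SpecError("subsequence length w must be >= 2")
        if self.stride < 1:
            raise SpecError("sampling stride l must be >= 1")
        if self.n_codewords < 1:
            raise SpecError("need at least one codeword")
        if self.sigma <= 0:
            raise SpecError("sigma must be > 0")
        if self.restarts < 1:
            raise SpecError("need at least one restart")
        if self.mode not in ("per_channel", "multivariate"):
            raise SpecError(f"unknown codebook mode {self.mode!r}")


@dataclass
class Codebook:
    """N codewords of dimension w (per-channel) or S*w (multivariate)."""

    codewords: np.ndarray            # (N, d)
    objective: float                 # sum of unsquared distances, selected restart
    config: CodebookConfig

    def __post_init__(self) -> None:
        self.codewords = np.asarray(self.codewords, dtype=float)
        if self.objective < 0:
            raise SpecError("objective must be >= 0")

    @property
    def n_codewords(self) -> int:
        return self.codewords.shape[0]


def extract_subsequences(x: np.ndarray, width: int, stride: int = 1) -> np.ndarray:
    """Sliding subsequences of a series (1-D) or frame (T x S, multivariate).

    Returns ``floor((T - w) / l) + 1`` rows; multivariate rows are the
    time-major (C-order) flattening of each ``w x S`` block.
    """
    x = np.asarray(x, dtype=float)
    T = x.shape[0]
    if T < width:
        raise InputError(f"series length {T} shorter than subsequence width {width}")
    windows = np.lib.stride_tricks.sliding_window_view(x, width, axis=0)[::stride]
    if x.ndim == 1:
        return windows.copy()                        # (S_sub, w)
    if x.ndim != 2:
        raise InputError("input must be 1-D or T x S")
    # windows: (S_sub, S, w) -> time-major (S_sub, w, S) -> flatten
    return windows.transpose(0, 2, 1).reshape(windows.shape[0], -1).copy()


def _lloyd(points: np.ndarray, n_clusters: int, rng: np.random.Generator,
           max_iter: int) -> tuple[np.ndarray, float]:
    """One Lloyd run from a random distinct-point initialization.

    Empty clusters are re-seeded with the point farthest from its assigned
    center.  Returns (centers, sum of unsquared Euclidean distances).
    """
    n = points.shape[0]
    centers = points[rng.choice(n, size=n_clusters, replace=False)].copy()
    assign = np.full(n, -1)
    for _ in range(max_iter):
        dist = cdist(points, centers)
        new_assign = dist.argmin(axis=1)             # ties -> lowest index
        for k in range(n_clusters):
            members = new_assign == k
            if members.any():
                centers[k] = points[members].mean(axis=0)
            else:
                far = dist[np.arange(n), new_assign].argmax()
                centers[k] = points[far]
                new_assign[far] = k
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    dist = cdist(points, centers)
    assign = dist.argmin(axis=1)
    objective = float(dist[np.arange(n), assign].sum())
    return centers, objective


def kmeans_codebook(subsequences: np.ndarray, config: CodebookConfig) -> Codebook:
    """Restarted k-means codebook construction.

    Runs Lloyd's algorithm ``config.restarts`` times from seeded random
    distinct-point initializations and keeps the restart whose sum of
    (unsquared) Euclidean distances between subsequences and their assigned
    centers is minimal; ties keep the first restart.  If
    ``max_subsequences`` is set, clustering operates on a seeded uniform
    sample of that size.
    """
    points = np.asarray(subsequences, dtype=float)
    if points.ndim != 2:
        raise InputError("subsequences must be a 2-D matrix")
    rng = np.random.default_rng(config.seed)
    if config.max_subsequences is not None and len(points) > config.max_subsequences:
        idx = rng.choice(len(points), size=config.max_subsequences, replace=False)
        points = points[idx]
    if len(points) < config.n_codewords:
        raise InputError(
            f"{len(points)} subsequences < N={config.n_codewords} codewords"
        )
    best_centers, best_objective = None, np.inf
    for _ in range(config.restarts):
        centers, objective = _lloyd(points, config.n_codewords, rng, config.max_iter)
        if objective < best_objective:                # strict: ties keep first
            best_centers, best_objective = centers, objective
    return Codebook(codewords=best_centers, objective=best_objective, config=config)


def hard_histogram(x: np.ndarray, codebook: Codebook,
                   width: int | None = None, stride: int | None = None) -> np.ndarray:
    """Normalized nearest-codeword frequency histogram (sums to 1)."""
    cfg = codebook.config
    subs = extract_subsequences(x, width or cfg.width, stride or cfg.stride)
    nearest = cdist(subs, codebook.codewords).argmin(axis=1)
    counts = np.bincount(nearest, minlength=codebook.n_codewords)
    return counts / counts.sum()


def soft_histogram(x: np.ndarray, codebook: Codebook,
                   width: int | None = None, stride: int | None = None,
                   sigma: float | None = None) -> np.ndarray:
    """Kernel-density smoothed codeword histogram.

    Each subsequence distributes one unit of mass over the codewords in
    proportion to ``exp(-D^2 / (2 sigma^2))``; per-subsequence normalization
    makes the histogram sum to exactly 1.  Evaluated as a max-shifted softmax
    of ``-D^2 / (2 sigma^2)``, which cannot underflow to an all-zero row.
    """
    cfg = codebook.config
    sigma = sigma if sigma is not None else cfg.sigma
    if sigma <= 0:
        raise SpecError("sigma must be > 0")
    subs = extract_subsequences(x, width or cfg.width, stride or cfg.stride)
    d2 = cdist(subs, codebook.codewords, metric="sqeuclidean")
    weights = softmax(-d2 / (2.0 * sigma ** 2), axis=1)
    return weights.mean(axis=0)


def build_codebooks(frameset: FrameSet, config: CodebookConfig) -> list[Codebook]:
    """Fit codebooks on a (training) frame set.

    ``per_channel`` mode returns one codebook per sensor channel (each fit on
    the pooled subsequences of that channel across frames); ``multivariate``
    returns a single-element list.
    """
    if config.mode == "per_channel":
        books = []
        for s in range(frameset.S):
            subs = np.concatenate([
                extract_subsequences(frameset.data[i][:, s], config.width, config.stride)
                for i in range(len(frameset))
            ])
            cfg = replace(config, seed=config.seed + s)
            books.append(kmeans_codebook(subs, cfg))
        return books
    subs = np.concatenate([
        extract_subsequences(frameset.data[i], config.width, config.stride)
        for i in range(len(frameset))
    ])
    return [kmeans_codebook(subs, config)]


def frame_feature(frame_matrix: np.ndarray, codebooks: list[Codebook],
                  config: CodebookConfig, soft: bool = False) -> np.ndarray:
    """Encode one frame: early-fused per-channel histograms or one
    multivariate histogram."""
    encode = soft_histogram if soft else hard_histogram
    if config.mode == "per_channel":
        if len(codebooks) != frame_matrix.shape[1]:
            raise SpecError(
                f"{len(codebooks)} codebooks for S={frame_matrix.shape[1]} channels"
            )
        return np.concatenate([
            encode(frame_matrix[:, s], codebooks[s]) for s in range(frame_matrix.shape[1])
        ])
    if len(codebooks) != 1:
        raise SpecError("multivariate mode takes exactly one codebook")
    return encode(frame_matrix, codebooks[0])


def encode_frameset(frameset: FrameSet, codebooks: list[Codebook],
                    config: CodebookConfig, soft: bool = False) -> FeatureMatrix:
    """Codeword-histogram feature matrix for a whole frame set."""
    n_dims = (frameset.S if config.mode == "per_channel" else 1) * config.n_codewords
    X = np.stack([
        frame_feature(frameset.data[i], codebooks, config, soft=soft)
        for i in range(len(frameset))
    ]) if len(frameset) else np.empty((0, n_dims))
    return FeatureMatrix(X=X, labels=frameset.labels.copy())
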