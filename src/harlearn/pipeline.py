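"""Method dispatch: fit a feature family on training frames, encode both splits.

The eight feature methods share one calling convention so the evaluation
protocol (and the CLI) can treat them uniformly:

====== ==========================================================
name   feature family
====== ==========================================================
hc     18 hand-crafted statistics per channel, min-max normalized
cbh    codeword histograms, hard assignment
cbs    codeword histograms, soft (kernel-density) assignment
mlp    penultimate dense activations of a trained MLP
cnn    penultimate dense activations of a trained CNN
lstm   penultimate dense activations of a trained 2-layer LSTM net
hybrid penultimate dense activations of a trained CNN-LSTM net
ae     encoder activations of a trained autoencoder
====== ==========================================================

Everything fit on data — normalization constants, codebooks, network
weights — is fit on the training split only.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import codebook as cb
from . import handcrafted as hc
from .errors import SpecError
from .io import FeatureMatrix, PipelineConfig
from .nn import (build_model, extract_features, get_preset, train_autoencoder,
                 train_supervised)
from .segment import FrameSet

METHODS = ("hc", "cbh", "cbs", "mlp", "cnn", "lstm", "hybrid", "ae")


def benchmark_config() -> PipelineConfig:
    """Desk-scale study conditions matching :func:`harlearn.synth.benchmark_spec`.

    T=32 windows (about 1 s at 30 Hz) slid with stride 16, per-channel
    codebooks of 16 codewords over w=8 subsequences (smoothing 0.5 g — the
    distance scale of neighboring codewords at this amplitude), the ``tiny``
    neural preset trained for 10 epochs with batch 64, and a fixed C=1 SVM.
    """
    return PipelineConfig(
        window=32, stride=16,
        cb_width=8, cb_stride=1, cb_codewords=16, cb_sigma=0.5,
        cb_restarts=10, cb_max_subsequences=4000,
        preset="tiny", epochs=10, batch_size=64,
        svm_c=1.0,
    )


def codebook_config(config: PipelineConfig) -> cb.CodebookConfig:
    return cb.CodebookConfig(
        width=config.cb_width, stride=config.cb_stride,
        n_codewords=config.cb_codewords, sigma=config.cb_sigma,
        mode=config.cb_mode, restarts=config.cb_restarts,
        max_subsequences=config.cb_max_subsequences, seed=config.seed,
    )


def learn_features(method: str, train: FrameSet, test: FrameSet,
                   config: PipelineConfig | None = None,
                   seed: int | None = None
                   ) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Fit the named feature method on ``train`` and encode both frame sets."""
    if method not in METHODS:
        raise SpecError(f"unknown feature method {method!r}; choose from {METHODS}")
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed

    if method == "hc":
        f_train = hc.compute_features(train)
        f_test = hc.compute_features(test)
        constants = hc.fit_minmax(f_train)
        return hc.apply_minmax(f_train, constants), hc.apply_minmax(f_test, constants)

    if method in ("cbh", "cbs"):
        cfg = replace(codebook_config(config), seed=seed)
        books = cb.build_codebooks(train, cfg)
        soft = method == "cbs"
        return (cb.encode_frameset(train, books, cfg, soft=soft),
                cb.encode_frameset(test, books, cfg, soft=soft))

    spec = get_preset(config.preset, "ae" if method == "ae" else method)
    n_classes = int(max(train.labels.max(), test.labels.max())) + 1
    model = build_model(spec, train.T, train.S, n_classes, seed=seed)
    if method == "ae":
        extractor = train_autoencoder(model, train, epochs=config.epochs,
                                      batch_size=config.batch_size, seed=seed)
    else:
        extractor = train_supervised(model, train, epochs=config.epochs,
                                     batch_size=config.batch_size, seed=seed)
    return extract_features(extractor, train), extract_features(extractor, test)
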