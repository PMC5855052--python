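"""Recording / feature-matrix containers and their delimited-text round trips.

A *recording* is a timestamp-indexed multichannel series: one row per sampling
time, ``S`` sensor-channel columns plus one integer label column.  Missing
sensor values are kept as explicit NaN markers (wireless sensors drop chunks
of data in real acquisitions; repairing them is the segmentation stage's job,
not the reader's).  The on-disk dialect is a comma-separated file with a
header row, preceded by one comment line carrying the sampling rate and
subject id::

    # harlearn-recording sample_rate_hz=30.0 subject_id=s1
    ch0,ch1,ch2,label
    0.12,-0.98,1.01,0
    ...
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import IntegrityError, ParseError, SchemaError, SpecError

_REC_MAGIC = "# harlearn-recording"


@dataclass
class SensorRecording:
    """A labeled multichannel sensor recording.

    Parameters
    ----------
    values : (T_total, S) float array
        Sensor samples in native units (e.g. g or m/s^2); NaN marks missing.
    labels : (T_total,) int array
        One class id per sampling time.
    sample_rate_hz : float
        Sampling frequency, > 0.
    channel_names : sequence of str
        One name per channel.
    subject_id : str
        Identifier of the subject the recording belongs to.
    """

    values: np.ndarray
    labels: np.ndarray
    sample_rate_hz: float
    channel_names: Sequence[str]
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise SpecError("values must be a (T_total, S) matrix")
        if len(self.labels) != len(self.values):
            raise IntegrityError(
                f"values ({len(self.values)} rows) and labels "
                f"({len(self.labels)}) must have equal length"
            )
        if self.sample_rate_hz <= 0:
            raise SpecError("sample_rate_hz must be positive")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.values.shape[1]:
            raise IntegrityError("one channel name per column required")
        if self.values.shape[1] < 1:
            raise SpecError("at least one sensor channel required")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(int)
            if not np.array_equal(as_int, self.labels):
                raise SchemaError("labels must be integer class ids")
            self.labels = as_int

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelMap:
    """Mapping between integer class ids and human-readable names."""

    names: dict[int, str]
    null_class_id: int | None = None

    def __post_init__(self) -> None:
        ids = sorted(self.names)
        if ids != list(range(len(ids))):
            raise SpecError("class ids must be unique and contiguous from 0")

    def name(self, class_id: int) -> str:
        return self.names[class_id]

    def id_of(self, name: str) -> int:
        for k, v in self.names.items():
            if v == name:
                return k
        raise KeyError(name)


@dataclass
class FeatureMatrix:
    """An ``n_frames x d`` feature table aligned with per-frame labels."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2:
            raise IntegrityError("feature matrix must be 2-D")
        if self.X.shape[0] != self.labels.shape[0]:
            raise IntegrityError(
                f"{self.X.shape[0]} feature rows vs {self.labels.shape[0]} labels"
            )
        if self.feature_names is not None and len(self.feature_names) != self.X.shape[1]:
            raise IntegrityError("one feature name per column required")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

def write_recording(recording: SensorRecording, path: str | Path) -> None:
    """Write a recording in the delimited-text dialect described above."""
    path = Path(path)
    df = pd.DataFrame(recording.values, columns=list(recording.channel_names))
    df["label"] = recording.labels
    with open(path, "w") as fh:
        fh.write(
            f"{_REC_MAGIC} sample_rate_hz={recording.sample_rate_hz!r} "
            f"subject_id={recording.subject_id}\n"
        )
        df.to_csv(fh, index=False, float_format="%.17g", na_rep="NaN")


def read_recording(
    path: str | Path,
    label_column: str = "label",
    channel_columns: Sequence[str] | None = None,
    sample_rate_hz: float | None = None,
    subject_id: str | None = None,
) -> SensorRecording:
    """Read a delimited-text recording.

    ``channel_columns`` restricts which columns become sensor channels
    (default: every non-label column).  Metadata from the comment header is
    used unless overridden by the keyword arguments.  Missing cells stay NaN.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(_REC_MAGIC):
        for token in first[len(_REC_MAGIC):].split():
            key, _, val = token.partition("=")
            meta[key] = val
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pandas messages include line numbers
        raise ParseError(f"{path}: {exc}") from exc
    if label_column not in df.columns:
        raise SchemaError(f"{path}: label column {label_column!r} not found")
    labels = df[label_column]
    if labels.isna().all():
        raise SchemaError(f"{path}: label column {label_column!r} is all-missing")
    if labels.isna().any():
        raise SchemaError(f"{path}: label column contains missing entries")
    if channel_columns is None:
        channel_columns = [c for c in df.columns if c != label_column]
    else:
        unknown = set(channel_columns) - set(df.columns)
        if unknown:
            raise SchemaError(f"{path}: unknown channel columns {sorted(unknown)}")
    values = df[list(channel_columns)].to_numpy(dtype=float)
    rate = sample_rate_hz
    if rate is None:
        rate = float(meta.get("sample_rate_hz", "nan"))
        if not np.isfinite(rate):
            raise SchemaError(
                f"{path}: no sample_rate_hz header; pass sample_rate_hz explicitly"
            )
    return SensorRecording(
        values=values,
        labels=labels.to_numpy().astype(int),
        sample_rate_hz=rate,
        channel_names=list(channel_columns),
        subject_id=subject_id or meta.get("subject_id", "s0"),
    )


# ---------------------------------------------------------------------------
# feature-matrix I/O
# ---------------------------------------------------------------------------

def write_features(features: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV (lossless for float64 at %.17g)."""
    names = features.feature_names or [f"f{i}" for i in range(features.n_features)]
    df = pd.DataFrame(features.X, columns=names)
    df["label"] = features.labels
    df.to_csv(path, index=False, float_format="%.17g", na_rep="NaN")


def read_features(path: str | Path) -> FeatureMatrix:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "label" not in df.columns:
        raise SchemaError(f"{path}: feature file lacks a 'label' column")
    names = [c for c in df.columns if c != "label"]
    X = df[names].to_numpy(dtype=float)
    if len(names) == 0:
        X = X.reshape(len(df), 0)
    return FeatureMatrix(X=X, labels=df["label"].to_numpy(dtype=int),
                         feature_names=names)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Flat bag of pipeline hyper-parameters.

    Defaults reproduce the body-worn multichannel setup: 30 Hz sampling,
    2 s-class windows of T=64 samples slid with stride 3, per-channel
    codebooks with w=24 / N=128 / l=1 and soft-assignment smoothing 256,
    ADADELTA training for 50 epochs with batch size 256, and a C grid of
    10^-3..10^3 for the linear SVM.
    """

    # segmentation
    window: int = 64
    stride: int = 3
    segment_mode: str = "sliding"          # {"sliding", "energy"}
    theta_high: float = 1.5                # g, energy-mode peak threshold
    theta_low: float = 1.0                 # g, previous-sample threshold
    # codebook
    cb_width: int = 24                     # subsequence length w
    cb_stride: int = 1                     # sampling stride l
    cb_codewords: int = 128                # N
    cb_sigma: float = 256.0                # soft-assignment smoothing
    cb_mode: str = "per_channel"           # {"per_channel", "multivariate"}
    cb_restarts: int = 10
    cb_max_subsequences: int | None = None
    # neural extractors
    preset: str = "opportunity"            # {"opportunity", "unimib", "tiny"}
    epochs: int = 50
    batch_size: int = 256
    # SVM
    svm_c: float | None = None             # None -> tune on the grid below
    c_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
    # global
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "c_grid" in raw:
            raw["c_grid"] = tuple(raw["c_grid"])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        data["c_grid"] = list(data["c_grid"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
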