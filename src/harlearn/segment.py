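"""Missing-data repair and frame segmentation.

Two segmentation modes are provided, mirroring the two acquisition styles the
pipeline supports:

* *sliding*: a fixed-length window of ``T`` samples slid with stride ``sigma``
  over a continuous labeled recording; each frame gets the majority label of
  its timestamps.
* *energy*: for triaxial accelerometer traces, frames of length ``T`` centered
  on acceleration peaks — samples where the magnitude exceeds ``theta_high``
  (1.5 g by default) after being below ``theta_low`` the sample before.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .errors import DataError, InputError, SpecError
from .io import SensorRecording


@dataclass
class Frame:
    """A fixed-size ``T x S`` window of consecutive samples with one label."""

    matrix: np.ndarray
    label: int
    start_index: int
    subject_id: str = "s0"


@dataclass
class FrameSet:
    """A stack of equally-shaped frames.

    Frames are stored densely as a ``(n, T, S)`` array; ``__getitem__``
    materializes :class:`Frame` views for convenience.
    """

    data: np.ndarray                      # (n, T, S)
    labels: np.ndarray                    # (n,)
    starts: np.ndarray                    # (n,)
    subjects: np.ndarray                  # (n,) str
    stride: int | None = None
    mode: str = "sliding"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.starts = np.asarray(self.starts, dtype=int)
        self.subjects = np.asarray(self.subjects)
        if self.data.ndim != 3:
            raise SpecError("frame data must be (n, T, S)")
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.starts) == len(self.subjects) == n):
            raise SpecError("labels/starts/subjects must match frame count")

    @property
    def T(self) -> int:
        return self.data.shape[1]

    @property
    def S(self) -> int:
        return self.data.shape[2]

    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i: int) -> Frame:
        return Frame(matrix=self.data[i], label=int(self.labels[i]),
                     start_index=int(self.starts[i]), subject_id=str(self.subjects[i]))

    def __iter__(self) -> Iterator[Frame]:
        for i in range(len(self)):
            yield self[i]

    @classmethod
    def concatenate(cls, framesets: Sequence["FrameSet"]) -> "FrameSet":
        if not framesets:
            raise SpecError("cannot concatenate zero framesets")
        T, S = framesets[0].T, framesets[0].S
        for fs in framesets:
            if (fs.T, fs.S) != (T, S):
                raise SpecError("all framesets must share T and S")
        return cls(
            data=np.concatenate([fs.data for fs in framesets]),
            labels=np.concatenate([fs.labels for fs in framesets]),
            starts=np.concatenate([fs.starts for fs in framesets]),
            subjects=np.concatenate([fs.subjects for fs in framesets]),
            stride=framesets[0].stride,
            mode=framesets[0].mode,
        )


def forward_fill(recording: SensorRecording) -> SensorRecording:
    """Replace missing values with the last non-missing one per channel.

    Leading missing samples (where no "last" value exists yet) are backfilled
    from the first valid sample of the channel.  Idempotent.  A channel with
    no valid sample at all cannot be repaired and raises :class:`DataError`.
    """
    values = recording.values
    all_missing = np.isnan(values).all(axis=0)
    if all_missing.any():
        bad = [recording.channel_names[i] for i in np.flatnonzero(all_missing)]
        raise DataError(f"channel(s) entirely missing: {bad}")
    if not np.isnan(values).any():
        return recording
    filled = values.copy()
    n = filled.shape[0]
    # vectorized last-observation-carried-forward
    idx = np.where(np.isnan(filled), -1, np.arange(n)[:, None])
    np.maximum.accumulate(idx, axis=0, out=idx)
    cols = np.arange(filled.shape[1])[None, :]
    filled = np.where(idx >= 0, filled[np.maximum(idx, 0), cols], np.nan)
    # leading gap: backfill from first valid sample
    lead = np.isnan(filled)
    if lead.any():
        first_valid = np.argmax(~np.isnan(values), axis=0)
        fill_row = values[first_valid, np.arange(values.shape[1])]
        filled = np.where(lead, fill_row[None, :], filled)
    return SensorRecording(
        values=filled, labels=recording.labels,
        sample_rate_hz=recording.sample_rate_hz,
        channel_names=list(recording.channel_names),
        subject_id=recording.subject_id,
    )


def drop_channels(recording: SensorRecording, names: Sequence[str]) -> SensorRecording:
    """Remove the named sensor channels, preserving the order of the rest."""
    unknown = [n for n in names if n not in recording.channel_names]
    if unknown:
        raise KeyError(f"unknown channel(s): {unknown}")
    keep = [i for i, n in enumerate(recording.channel_names) if n not in set(names)]
    return SensorRecording(
        values=recording.values[:, keep],
        labels=recording.labels,
        sample_rate_hz=recording.sample_rate_hz,
        channel_names=[recording.channel_names[i] for i in keep],
        subject_id=recording.subject_id,
    )


def majority_label(labels: np.ndarray) -> int:
    """Most frequent label of a window.

    Ties are broken in favor of the candidate whose *last occurrence* in the
    window is latest — deterministic, and it favors the activity in progress
    at the end of the window.
    """
    labels = np.asarray(labels)
    if labels.size < 1:
        raise InputError("majority_label needs at least one label")
    uniq, counts = np.unique(labels, return_counts=True)
    best = uniq[counts == counts.max()]
    if len(best) == 1:
        return int(best[0])
    last_pos = {int(l): i for i, l in enumerate(labels)}
    return int(max(best, key=lambda l: last_pos[int(l)]))


def sliding_window_segment(recording: SensorRecording, T: int, stride: int) -> FrameSet:
    """Cut a recording into half-open windows ``[t, t+T)`` at starts 0, stride, 2*stride...

    The frame count is exactly ``floor((T_total - T)/stride) + 1``; trailing
    partial windows are discarded.  Each frame is labeled by
    :func:`majority_label` over its timestamps.
    """
    if stride < 1:
        raise SpecError("stride must be >= 1")
    if T < 1:
        raise SpecError("window length T must be >= 1")
    values = recording.values
    if np.isnan(values).any():
        raise InputError("recording contains missing values; run forward_fill first")
    T_total = recording.n_samples
    if T > T_total:
        warnings.warn(
            f"window T={T} exceeds recording length {T_total}; returning empty set",
            stacklevel=2,
        )
        return FrameSet(
            data=np.empty((0, T, recording.n_channels)),
            labels=np.empty(0, dtype=int), starts=np.empty(0, dtype=int),
            subjects=np.empty(0, dtype=object), stride=stride, mode="sliding",
        )
    starts = np.arange(0, T_total - T + 1, stride)
    windows = np.lib.stride_tricks.sliding_window_view(values, T, axis=0)
    data = windows[starts].transpose(0, 2, 1).copy()   # (n, T, S)
    labels = np.array([majority_label(recording.labels[s:s + T]) for s in starts])
    return FrameSet(
        data=data, labels=labels, starts=starts,
        subjects=np.full(len(starts), recording.subject_id, dtype=object),
        stride=stride, mode="sliding",
    )


def energy_peak_segment(
    recording: SensorRecording,
    T: int,
    theta_high: float = 1.5,
    theta_low: float = 1.0,
    axes: Sequence[int] | None = None,
) -> FrameSet:
    """Extract frames centered on acceleration peaks.

    The magnitude ``m(t) = sqrt(sum over axes of x^2)`` of a 3-channel
    accelerometer trace is scanned; a peak fires at ``t`` when
    ``m(t) > theta_high`` and ``m(t-1) < theta_low``.  One frame of length
    ``T`` with ``T // 2`` samples before the peak (for odd T the peak is the
    exact center) is cut for each retained peak.  Peaks whose window would
    cross a recording boundary are discarded, as are peaks closer than
    ``T // 2`` samples to an earlier retained peak (the earlier one wins).
    Frames are labeled with the label at the peak timestamp.
    """
    if axes is None:
        if recording.n_channels != 3:
            raise SpecError(
                f"energy segmentation needs 3 accelerometer axes (got "
                f"S={recording.n_channels}); pass `axes` to select a subset"
            )
        axes = (0, 1, 2)
    if len(axes) != 3:
        raise SpecError("`axes` must name exactly 3 channels")
    values = recording.values
    if np.isnan(values).any():
        raise InputError("recording contains missing values; run forward_fill first")
    mag = np.sqrt((values[:, list(axes)] ** 2).sum(axis=1))
    t = np.arange(1, len(mag))
    candidates = t[(mag[1:] > theta_high) & (mag[:-1] < theta_low)]
    before = T // 2
    retained: list[int] = []
    for peak in candidates:
        start = peak - before
        if start < 0 or start + T > len(mag):
            continue                       # too close to a boundary
        if retained and peak - retained[-1] < T // 2:
            continue                       # too close to the previous peak
        retained.append(int(peak))
    starts = np.array([p - before for p in retained], dtype=int)
    data = np.stack([values[s:s + T] for s in starts]) if retained else \
        np.empty((0, T, recording.n_channels))
    labels = recording.labels[retained] if retained else np.empty(0, dtype=int)
    return FrameSet(
        data=data, labels=np.asarray(labels, dtype=int), starts=starts,
        subjects=np.full(len(retained), recording.subject_id, dtype=object),
        stride=None, mode="energy",
    )
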