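"""Synthetic labeled sensor recordings with the structure the pipeline assumes.

Two acquisition styles are emulated:

* long continuous multichannel recordings in which scripted activity bouts
  alternate with a dominant background (NULL) class, sensor channels carry
  class-specific oscillatory signatures, and wireless dropouts leave
  contiguous chunks of missing values;
* short triaxial accelerometer traces containing sharp acceleration
  transients (falls) that exceed 1.5 g, for the energy-based segmentation
  mode.

Every activity class is a sum of up to a few sinusoids per channel plus
Gaussian noise and a constant (gravity-like) offset.  Classes with disjoint
frequency content have distinct spectral-energy and autocorrelation
signatures, so all feature families in the toolkit are discriminative in
principle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SpecError
from .io import SensorRecording

NULL_CLASS = 0


@dataclass
class ActivityProfile:
    """Signal signature of one activity class.

    ``components[s]`` lists ``(amplitude_g, frequency_hz, phase_rad)``
    sinusoid triples for channel ``s``.
    """

    class_id: int
    components: list[list[tuple[float, float, float]]]
    noise_sd: float = 0.05                  # g
    mean_offset: float = 0.0                # g
    bout_duration_range: tuple[float, float] = (2.0, 6.0)   # seconds

    def validate(self, sample_rate_hz: float, n_channels: int) -> None:
        if self.class_id == NULL_CLASS:
            raise SpecError(f"class id {NULL_CLASS} is reserved for NULL")
        if len(self.components) != n_channels:
            raise SpecError(
                f"profile {self.class_id}: {len(self.components)} channel "
                f"component lists for S={n_channels}"
            )
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        lo, hi = self.bout_duration_range
        if not 0 < lo <= hi:
            raise SpecError("bout_duration_range must satisfy 0 < lo <= hi")
        for per_channel in self.components:
            for _, freq, _ in per_channel:
                if freq >= sample_rate_hz / 2:
                    raise SpecError(
                        f"component frequency {freq} Hz violates Nyquist at "
                        f"{sample_rate_hz} Hz"
                    )

    def signal(self, t: np.ndarray, n_channels: int) -> np.ndarray:
        """Noise-free waveform at times ``t`` (seconds); shape (len(t), S)."""
        out = np.full((len(t), n_channels), self.mean_offset, dtype=float)
        for s, per_channel in enumerate(self.components):
            for amp, freq, phase in per_channel:
                out[:, s] += amp * np.sin(2 * np.pi * freq * t + phase)
        return out


@dataclass
class SimulationSpec:
    """Conditions of one simulated acquisition session."""

    profiles: list[ActivityProfile]
    null_fraction: float = 0.4
    total_duration: float = 600.0           # seconds
    sample_rate_hz: float = 30.0
    n_channels: int = 6
    missing_rate: float = 0.0
    null_noise_sd: float = 0.05             # g, background jitter
    seed: int = 0

    def validate(self) -> None:
        ids = [p.class_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise SpecError("profile class ids must be unique")
        if not 0 <= self.null_fraction < 1:
            raise SpecError("null_fraction must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise SpecError("missing_rate must be in [0, 1)")
        if not self.profiles:
            raise SpecError("at least one activity profile required")
        for p in self.profiles:
            p.validate(self.sample_rate_hz, self.n_channels)
        max_bout = max(p.bout_duration_range[1] for p in self.profiles)
        if self.total_duration < max_bout:
            raise SpecError(
                f"total_duration {self.total_duration}s shorter than one bout "
                f"({max_bout}s)"
            )


def generate_recording(spec: SimulationSpec, seed: int | None = None) -> SensorRecording:
    """Simulate a continuous labeled recording.

    Labels form piecewise-constant activity bouts separated by NULL spans;
    each activity class receives an equal share of the non-NULL time (classes
    are scheduled greedily by largest remaining deficit, so empirical
    proportions track the spec closely).  Deterministic for a given seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    fs = spec.sample_rate_hz
    n_total = int(round(spec.total_duration * fs))
    active_share = (1.0 - spec.null_fraction) / len(spec.profiles)

    labels = np.zeros(n_total, dtype=int)
    pieces: list[tuple[int, int, ActivityProfile | None]] = []  # (start, stop, profile)
    budget = {p.class_id: active_share * n_total for p in spec.profiles}
    by_id = {p.class_id: p for p in spec.profiles}
    # mean NULL span keeping the null/active ratio, clipped to stay positive
    null_active_ratio = spec.null_fraction / max(1.0 - spec.null_fraction, 1e-12)

    t = 0
    spent = {p.class_id: 0 for p in spec.profiles}
    while t < n_total:
        # NULL span first (transitions pass through NULL)
        if spec.null_fraction > 0:
            mean_bout = np.mean([np.mean(p.bout_duration_range) for p in spec.profiles])
            null_len = int(round(rng.uniform(0.5, 1.5) * mean_bout
                                 * null_active_ratio * fs))
            null_len = min(null_len, n_total - t)
            t += null_len
        if t >= n_total:
            break
        # activity with the largest remaining deficit
        cid = max(budget, key=lambda c: budget[c] - spent[c])
        prof = by_id[cid]
        lo, hi = prof.bout_duration_range
        bout = int(round(rng.uniform(lo, hi) * fs))
        bout = min(bout, n_total - t)
        labels[t:t + bout] = cid
        pieces.append((t, t + bout, prof))
        spent[cid] += bout
        t += bout

    # waveforms
    times = np.arange(n_total) / fs
    values = rng.normal(0.0, spec.null_noise_sd, size=(n_total, spec.n_channels))
    for start, stop, prof in pieces:
        seg = prof.signal(times[start:stop], spec.n_channels)
        if prof.noise_sd > 0:
            seg = seg + rng.normal(0.0, prof.noise_sd, size=seg.shape)
        values[start:stop] = seg

    rec = SensorRecording(
        values=values, labels=labels, sample_rate_hz=fs,
        channel_names=[f"ch{i}" for i in range(spec.n_channels)],
        subject_id=f"sim{spec.seed if seed is None else seed}",
    )
    if spec.missing_rate > 0:
        rec = inject_missing(rec, spec.missing_rate, mean_gap=10,
                             seed=int(rng.integers(2**31)))
    return rec


def inject_missing(
    recording: SensorRecording, rate: float, mean_gap: int = 10,
    seed: int = 0,
) -> SensorRecording:
    """Blank contiguous runs of samples so a fraction ``rate`` of cells is missing.

    Gaps are modeled as a two-state Markov chain per channel: outside a gap a
    new gap opens with probability ``rate / ((1 - rate) * mean_gap)``; gap
    lengths are geometric with mean ``mean_gap``.  The stationary missing
    fraction is then ``rate``.
    """
    if not 0 <= rate < 1:
        raise SpecError("rate must be in [0, 1)")
    if rate == 0:
        return recording
    if mean_gap < 1:
        raise SpecError("mean_gap must be >= 1")
    rng = np.random.default_rng(seed)
    n, S = recording.values.shape
    p_open = rate / ((1.0 - rate) * mean_gap)
    p_close = 1.0 / mean_gap
    values = recording.values.copy()
    for s in range(S):
        mask = np.zeros(n, dtype=bool)
        t = 0
        while t < n:
            # geometric waiting time to the next gap, then a geometric gap
            wait = rng.geometric(min(p_open, 1.0))
            t += wait
            if t >= n:
                break
            gap = rng.geometric(p_close)
            mask[t:t + gap] = True
            t += gap
        values[mask, s] = np.nan
    return SensorRecording(
        values=values, labels=recording.labels,
        sample_rate_hz=recording.sample_rate_hz,
        channel_names=list(recording.channel_names),
        subject_id=recording.subject_id,
    )


def generate_fall_recording(
    n_events: int,
    T: int,
    peak_amplitude: float,
    spec: SimulationSpec | None = None,
    fall_class_ids: Sequence[int] = (1,),
    seed: int = 0,
) -> SensorRecording:
    """Simulate a triaxial accelerometer trace containing sharp fall transients.

    The baseline magnitude sits just below 1 g (gravity on one axis); each of
    the ``n_events`` events adds a short half-sine burst on that axis whose
    peak reaches ``peak_amplitude`` g, rising from below 1 g to above 1.5 g
    within one sample so an energy-based segmenter triggers exactly once per
    event.  Events are spaced ``2 T`` samples apart, at least ``T`` from the
    boundaries.  Event samples carry fall class labels (cycling through
    ``fall_class_ids``); everything else is NULL.
    """
    if peak_amplitude <= 1.5:
        raise SpecError("peak_amplitude must exceed the 1.5 g detection threshold")
    if n_events < 1:
        raise SpecError("n_events must be >= 1")
    if T < 8:
        raise SpecError("T too short for an event-centered frame")
    rng = np.random.default_rng(seed)
    fs = spec.sample_rate_hz if spec is not None else 50.0
    n_total = 2 * T * (n_events + 1)
    if spec is not None and spec.total_duration is not None:
        requested = int(round(spec.total_duration * fs))
        if requested < n_total:
            raise SpecError(
                f"{n_events} events with T={T} need {n_total} samples; "
                f"spec allows only {requested}"
            )
        n_total = requested

    baseline = 0.97
    values = rng.normal(0.0, 0.004, size=(n_total, 3))
    values[:, 2] += baseline               # gravity on the z axis
    labels = np.zeros(n_total, dtype=int)

    burst_len = 5
    # impact-like burst: the rise is faster than one 50 Hz sampling interval,
    # so the magnitude jumps from below 1 g straight to the peak and then
    # decays along a quarter sine — guarantees a below-1g -> above-1.5g jump
    shape = np.cos(np.pi * np.arange(burst_len) / (2 * (burst_len - 1)))
    peaks = []
    for k in range(n_events):
        center = 2 * T * (k + 1)
        start = center - burst_len // 2
        amp = peak_amplitude - baseline
        values[start:start + burst_len, 2] += amp * shape
        labels[start:start + burst_len] = fall_class_ids[k % len(fall_class_ids)]
        peaks.append(start)
    return SensorRecording(
        values=values, labels=labels, sample_rate_hz=fs,
        channel_names=["acc_x", "acc_y", "acc_z"],
        subject_id=f"fall{seed}",
    )


# ---------------------------------------------------------------------------
# the easy benchmark: fixed study conditions for end-to-end recovery tests
# ---------------------------------------------------------------------------

def benchmark_spec(seed: int = 0, total_duration: float = 400.0,
                   n_channels: int = 6) -> SimulationSpec:
    """Three well-separated activity classes plus NULL on six channels.

    Classes oscillate at 1.2, 3.1 and 6.3 Hz (disjoint, all far below the
    15 Hz Nyquist limit at 30 Hz sampling) with class-specific offsets and
    per-channel amplitude/phase variation; noise is 0.05 g.
    """
    freqs = [1.2, 3.1, 6.3]
    offsets = [0.3, -0.3, 0.1]
    profiles = []
    for k, (f0, off) in enumerate(zip(freqs, offsets), start=1):
        comps = []
        for s in range(n_channels):
            amp = 0.6 + 0.4 * ((s + k) % 3) / 2.0
            phase = 0.5 * s + 0.3 * k
            comps.append([(amp, f0, phase), (0.2 * amp, 2 * f0, phase / 2)])
        profiles.append(ActivityProfile(
            class_id=k, components=comps, noise_sd=0.05, mean_offset=off,
            bout_duration_range=(2.0, 6.0),
        ))
    return SimulationSpec(
        profiles=profiles, null_fraction=0.4, total_duration=total_duration,
        sample_rate_hz=30.0, n_channels=n_channels, seed=seed,
    )


def benchmark_recordings(
    seed: int = 0, train_duration: float = 400.0, test_duration: float = 200.0,
) -> tuple[SensorRecording, SensorRecording]:
    """Train/test recordings drawn from the benchmark conditions."""
    train = generate_recording(benchmark_spec(seed, train_duration))
    test = generate_recording(benchmark_spec(seed + 1, test_duration))
    return train, test
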