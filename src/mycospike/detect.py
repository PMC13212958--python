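"""Threshold-and-duration spike detection and spike-morphology summaries.

Spikes here are slow extracellular events (tens of seconds to tens of
minutes, millivolt scale), not neuronal action potentials.  A spike on a
channel is a maximal run of consecutive samples with

    V(t) > baseline + k * sigma

kept only if the run lasts at least ``w_min`` seconds.  Baseline is the
channel's full-series median and sigma its full-series standard deviation
(:func:`mycospike.recording.compute_channel_stats`); the defaults k = 2.0 and
w_min = 60 s are the fixed parameters of the reference analysis.  Width is
the run length times the sampling interval (a 60-sample run at 1 Hz is
exactly 60 s) and amplitude is the maximum deviation from baseline within
the run.  A sampling gap terminates any open run, so events never span a
recording discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .recording import GAP_FACTOR, ChannelStats, Recording, compute_channel_stats

__all__ = [
    "DetectionParams",
    "SpikeEvent",
    "SpikeShapeSummary",
    "detect_spikes",
    "detect_all_channels",
    "summarize_spikes",
    "average_spike_shape",
    "events_to_frame",
    "write_spike_table",
]


@dataclass(frozen=True)
class DetectionParams:
    """Amplitude and duration criteria of the spike definition.

    k
        Threshold multiplier on the channel's standard deviation; the
        amplitude condition is V > baseline + k*sigma.
    w_min
        Minimum supra-threshold duration in seconds.
    negative_polarity
        Detect mirrored negative-going excursions (V < baseline - k*sigma)
        instead of the default positive condition.  Off by default: only the
        positive condition is part of the reference definition.
    """

    k: float = 2.0
    w_min: float = 60.0
    negative_polarity: bool = False

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.w_min <= 0:
            raise ValueError("w_min must be positive")


@dataclass(frozen=True)
class SpikeEvent:
    """One supra-threshold event on one channel.

    ``onset`` is the time of the first sample above threshold and
    ``termination`` the time of the last contiguous sample above threshold.
    ``width`` counts the run length in units of the sampling interval, and
    ``amplitude`` is max(V - baseline) over the run.
    """

    channel: int
    onset: float
    termination: float
    width: float
    amplitude: float
    peak_time: float

    def __post_init__(self) -> None:
        if self.termination < self.onset:
            raise ValueError("termination precedes onset")
        if not self.onset <= self.peak_time <= self.termination:
            raise ValueError("peak_time outside [onset, termination]")


@dataclass(frozen=True)
class SpikeShapeSummary:
    """Onset-aligned, peak-normalised average spike waveform with IQR band."""

    time_grid: np.ndarray  # seconds relative to onset
    mean_waveform: np.ndarray  # unitless, each contributor peaks at 1
    q25: np.ndarray
    q75: np.ndarray
    n_events: int
    n_dropped: int  # events truncated by record edges, excluded


def _contiguous_runs(above: np.ndarray, times: np.ndarray, dt: float) -> list[tuple[int, int]]:
    """Maximal runs of True in ``above``; a time step > GAP_FACTOR*dt breaks a run."""
    runs: list[tuple[int, int]] = []
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return runs
    # split where index advance or time advance breaks contiguity
    breaks = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(times[idx]) > GAP_FACTOR * dt)
    )
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    for a, b in zip(starts, stops):
        runs.append((int(idx[a]), int(idx[b])))
    return runs


def detect_spikes(
    recording: Recording,
    channel: int,
    params: DetectionParams | None = None,
    *,
    stats: ChannelStats | None = None,
) -> list[SpikeEvent]:
    """Detect spikes on one channel.

    Returns events ordered by onset; they are maximal supra-threshold runs,
    hence non-overlapping, each at least ``w_min`` long.  ``stats`` may be
    supplied to reuse cached channel statistics or to impose an explicit
    baseline/sigma; by default they are computed from the full series.

    Raises ``ValueError`` on a zero-variance channel, where the threshold is
    undefined.
    """
    params = params or DetectionParams()
    if stats is None:
        stats = compute_channel_stats(recording, channel)
    if stats.sigma == 0:
        raise ValueError(
            f"channel {channel}: zero variance, threshold undefined"
        )
    series = recording.channel(channel)
    if params.negative_polarity:
        series = 2 * stats.baseline - series  # mirror about baseline
    threshold = stats.threshold(params.k)
    above = series > threshold
    dt = recording.sampling_interval

    events: list[SpikeEvent] = []
    for start, stop in _contiguous_runs(above, recording.times, dt):
        n = stop - start + 1
        width = n * dt
        if width < params.w_min:
            continue
        segment = series[start : stop + 1] - stats.baseline
        peak_idx = int(np.argmax(segment))
        events.append(
            SpikeEvent(
                channel=channel,
                onset=float(recording.times[start]),
                termination=float(recording.times[stop]),
                width=float(width),
                amplitude=float(segment[peak_idx]),
                peak_time=float(recording.times[start + peak_idx]),
            )
        )
    return events


def detect_all_channels(
    recording: Recording, params: DetectionParams | None = None
) -> list[list[SpikeEvent]]:
    """Run :func:`detect_spikes` on every channel; zero-variance channels yield []."""
    out = []
    for c in range(recording.n_channels):
        try:
            out.append(detect_spikes(recording, c, params))
        except ValueError:
            out.append([])
    return out


def summarize_spikes(events: Sequence[SpikeEvent]) -> pd.DataFrame:
    """Distribution summary (mean, median, sd, IQR) of widths and amplitudes.

    Medians are reported alongside means because both distributions are
    strongly right-skewed.  An empty event list yields an all-NaN frame with
    n = 0 rather than an error.
    """
    rows = {}
    for name, values in (
        ("width_s", np.array([e.width for e in events], dtype=float)),
        ("amplitude_mV", np.array([e.amplitude for e in events], dtype=float)),
    ):
        if values.size:
            q25, q75 = np.percentile(values, [25, 75])
            rows[name] = dict(
                n=values.size,
                mean=values.mean(),
                median=float(np.median(values)),
                sd=float(values.std()),
                q25=float(q25),
                q75=float(q75),
            )
        else:
            rows[name] = dict(n=0, mean=np.nan, median=np.nan, sd=np.nan,
                              q25=np.nan, q75=np.nan)
    return pd.DataFrame(rows).T


def average_spike_shape(
    recording: Recording,
    events: Sequence[SpikeEvent],
    window: tuple[float, float] = (-60.0, 1200.0),
    *,
    stats: dict[int, ChannelStats] | None = None,
) -> SpikeShapeSummary:
    """Onset-aligned, peak-normalised mean waveform with pointwise IQR.

    Each event's segment over ``window`` (seconds relative to onset) is
    divided by the event amplitude after baseline subtraction, so each
    contributing waveform peaks at exactly 1 inside its supra-threshold run.
    Events whose window extends past the record edges are dropped and
    counted in ``n_dropped``.  The default window (-60 s to +1200 s) spans
    the observed spike-width range.  ``stats`` may map channel index to the
    :class:`ChannelStats` used at detection time so the same baseline is
    subtracted here; by default stats are recomputed from the recording.
    """
    if not events:
        raise ValueError("average_spike_shape requires at least one event")
    dt = recording.sampling_interval
    pre = int(round(window[0] / dt))
    post = int(round(window[1] / dt))
    grid = np.arange(pre, post + 1) * dt

    t0 = recording.times[0]
    waveforms = []
    dropped = 0
    stats_cache: dict[int, ChannelStats] = dict(stats) if stats else {}
    for ev in events:
        if ev.channel not in stats_cache:
            stats_cache[ev.channel] = compute_channel_stats(recording, ev.channel)
        onset_idx = int(round((ev.onset - t0) / dt))
        lo, hi = onset_idx + pre, onset_idx + post
        if lo < 0 or hi >= recording.n_samples:
            dropped += 1
            continue
        seg = recording.channel(ev.channel)[lo : hi + 1]
        baseline = stats_cache[ev.channel].baseline
        waveforms.append((seg - baseline) / ev.amplitude)
    if not waveforms:
        raise ValueError("all events truncated by record edges")
    stack = np.vstack(waveforms)
    q25, q75 = np.percentile(stack, [25, 75], axis=0)
    return SpikeShapeSummary(
        time_grid=grid,
        mean_waveform=stack.mean(axis=0),
        q25=q25,
        q75=q75,
        n_events=len(waveforms),
        n_dropped=dropped,
    )


def events_to_frame(events: Sequence[SpikeEvent]) -> pd.DataFrame:
    """Spike table with columns channel, onset_s, termination_s, width_s,
    amplitude_mV, peak_time_s."""
    return pd.DataFrame(
        [
            dict(
                channel=e.channel,
                onset_s=e.onset,
                termination_s=e.termination,
                width_s=e.width,
                amplitude_mV=e.amplitude,
                peak_time_s=e.peak_time,
            )
            for e in events
        ],
        columns=["channel", "onset_s", "termination_s", "width_s",
                 "amplitude_mV", "peak_time_s"],
    )


def write_spike_table(events: Sequence[SpikeEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)
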