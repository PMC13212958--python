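"""Point-process view of each channel: ISI, regularity, and burst statistics.

Once spikes are detected, each channel is reduced to an ordered sequence of
spike onset times (a spike train).  Inter-spike intervals ISI_i = t_{i+1} -
t_i carry the temporal structure; their coefficient of variation CV =
sd/mean separates near-periodic activity (CV ~ 0) from Poisson-like
irregularity (CV ~ 1).  Bursts are runs of two or more spikes whose
separating ISIs are each below 30% of the channel's own median ISI — the
threshold always uses the channel's median over the full recording, never a
pooled one.  No stationarity assumption or windowed correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import SpikeEvent

__all__ = [
    "SpikeTrain",
    "ISIStats",
    "Burst",
    "trains_from_events",
    "compute_isis",
    "isi_stats",
    "detect_bursts",
    "raster",
    "isi_summary_table",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike onset times of one channel."""

    channel: int
    onsets: np.ndarray  # seconds, strictly increasing
    duration: float  # recording length in seconds

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if onsets.size and (onsets[0] < 0 or onsets[-1] > self.duration):
            raise ValueError("onsets must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.onsets.size)


@dataclass(frozen=True)
class ISIStats:
    intervals: np.ndarray
    mean: float
    median: float
    sd: float
    cv: float  # sd/mean; NaN when undefined
    heavy_tailed: bool  # median < mean, flagging right skew

    @property
    def n(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class Burst:
    """A maximal run of spikes separated by sub-threshold ISIs."""

    member_indices: tuple[int, ...]  # positions of spikes in the train
    start: float
    end: float

    @property
    def size(self) -> int:
        return len(self.member_indices)


def trains_from_events(
    events_per_channel: Sequence[Sequence[SpikeEvent]], duration: float
) -> list[SpikeTrain]:
    return [
        SpikeTrain(
            channel=c,
            onsets=np.array([e.onset for e in evs], dtype=float),
            duration=duration,
        )
        for c, evs in enumerate(events_per_channel)
    ]


def compute_isis(train: SpikeTrain) -> np.ndarray:
    """Intervals between onsets of successive spikes; length max(0, n-1)."""
    return np.diff(train.onsets)


def isi_stats(intervals: np.ndarray) -> ISIStats:
    """Mean, median, sd and CV of a set of intervals.

    An empty input returns an explicit empty-stats value (all NaN, n = 0)
    rather than raising; CV is NaN when the mean is not positive.
    """
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size == 0:
        return ISIStats(intervals, np.nan, np.nan, np.nan, np.nan, False)
    mean = float(intervals.mean())
    median = float(np.median(intervals))
    sd = float(intervals.std())
    cv = sd / mean if mean > 0 else np.nan
    return ISIStats(intervals, mean, median, sd, cv, heavy_tailed=median < mean)


def detect_bursts(
    train: SpikeTrain, fraction: float = 0.30
) -> tuple[list[Burst], float]:
    """Bursts under the fraction-of-median-ISI rule.

    The burst threshold is ``fraction`` times the channel's median ISI.
    Maximal runs of consecutive ISIs strictly below the threshold define
    bursts; both endpoints of each qualifying ISI are members, so every
    burst has at least two spikes.  Returns the bursts and the burst
    fraction (share of the train's spikes that belong to some burst).

    Trains with fewer than 3 onsets cannot define a median ISI over ≥2
    intervals and yield ``([], 0.0)``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if train.n_spikes < 3:
        return [], 0.0
    isis = compute_isis(train)
    threshold = fraction * float(np.median(isis))
    below = isis < threshold

    bursts: list[Burst] = []
    members: set[int] = set()
    i = 0
    while i < below.size:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < below.size and below[j + 1]:
            j += 1
        idx = tuple(range(i, j + 2))  # ISIs i..j involve spikes i..j+1
        bursts.append(
            Burst(member_indices=idx,
                  start=float(train.onsets[idx[0]]),
                  end=float(train.onsets[idx[-1]]))
        )
        members.update(idx)
        i = j + 1
    return bursts, len(members) / train.n_spikes


def raster(
    trains: Sequence[SpikeTrain], window: tuple[float, float]
) -> dict[int, np.ndarray]:
    """Per-channel onset lists restricted to ``window = (t0, t1)``.

    Channel ordering is preserved; output maps channel index to the onsets
    with t0 <= t < t1, ready for plotting or two-column export.
    """
    t0, t1 = window
    if not t0 < t1:
        raise ValueError("window must satisfy t0 < t1")
    return {
        tr.channel: tr.onsets[(tr.onsets >= t0) & (tr.onsets < t1)]
        for tr in trains
    }


def isi_summary_table(trains: Sequence[SpikeTrain]) -> pd.DataFrame:
    """Per-channel and pooled ISI/burst summary.

    The pooled row concatenates intervals across channels (the pooled CV
    uses pooled intervals), while burst statistics always use each
    channel's own median ISI.
    """
    rows = []
    pooled: list[np.ndarray] = []
    total_spikes = 0
    total_burst_members = 0
    for tr in trains:
        isis = compute_isis(tr)
        pooled.append(isis)
        stats = isi_stats(isis)
        bursts, bfrac = detect_bursts(tr) if tr.n_spikes >= 3 else ([], 0.0)
        total_spikes += tr.n_spikes
        total_burst_members += round(bfrac * tr.n_spikes)
        rows.append(dict(channel=tr.channel, n_spikes=tr.n_spikes,
                         isi_mean=stats.mean, isi_median=stats.median,
                         isi_sd=stats.sd, cv=stats.cv,
                         n_bursts=len(bursts), burst_fraction=bfrac))
    pooled_stats = isi_stats(np.concatenate(pooled) if pooled else np.array([]))
    rows.append(dict(channel="pooled",
                     n_spikes=total_spikes,
                     isi_mean=pooled_stats.mean, isi_median=pooled_stats.median,
                     isi_sd=pooled_stats.sd, cv=pooled_stats.cv,
                     n_bursts=np.nan,
                     burst_fraction=(total_burst_members / total_spikes
                                     if total_spikes else 0.0)))
    return pd.DataFrame(rows)
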