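"""Reading, validation and per-channel statistics of multichannel logger recordings.

A recording is a uniformly sampled multivariate time series of differential
electrical potentials (mV) from an ordered linear electrode array.  Channel
order corresponds to physical position along the array axis; adjacent channel
centres are ``spacing_cm`` apart (2 cm by default).  Two text dialects are
supported:

``plain``
    First column is time in seconds, remaining columns are per-channel
    potentials.  This is the canonical dialect used for fixtures and output.
``timestamped``
    First column is an ISO-like timestamp (anything ``pandas.to_datetime``
    accepts), remaining columns are per-channel potentials.  Timestamps are
    converted to continuous seconds relative to the first sample.

No detrending, smoothing or frequency-domain filtering is ever applied; the
baseline of a channel is the median of its full raw series and variability is
the standard deviation of the full raw series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "ChannelStats",
    "ValidationReport",
    "read_recording",
    "write_recording",
    "compute_channel_stats",
    "validate_recording",
]

#: unit of the output potentials; input dialects may declare another source unit
_UNIT_TO_MV = {"mV": 1.0, "V": 1000.0, "uV": 1e-3}

#: a step between consecutive samples larger than this multiple of the nominal
#: sampling interval is reported as a gap and breaks run contiguity downstream
GAP_FACTOR = 1.5


@dataclass(frozen=True)
class Recording:
    """Multichannel differential-potential recording on a uniform time grid."""

    channel_labels: tuple[str, ...]
    times: np.ndarray  # seconds since first sample, strictly increasing
    potentials: np.ndarray  # shape (n_samples, n_channels), mV
    sampling_interval: float = 1.0  # seconds
    spacing_cm: float = 2.0  # distance between adjacent channel centres

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pots = np.asarray(self.potentials, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "potentials", pots)
        if pots.ndim != 2:
            raise ValueError("potentials must be a 2-D (n_samples, n_channels) array")
        if pots.shape[0] != times.shape[0]:
            raise ValueError("times and potentials disagree on sample count")
        if pots.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels and potentials disagree on channel count")
        if pots.shape[1] < 2:
            raise ValueError("a recording needs at least 2 channels")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.spacing_cm <= 0:
            raise ValueError("spacing_cm must be positive")

    @property
    def n_channels(self) -> int:
        return self.potentials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.potentials.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds (last minus first sample time)."""
        return float(self.times[-1] - self.times[0]) if self.times.size else 0.0

    def channel(self, index: int) -> np.ndarray:
        """Potential series of one channel, by position along the array."""
        return self.potentials[:, index]

    def gaps(self) -> list[tuple[float, float]]:
        """Time ranges ``(t_before, t_after)`` where the grid skips samples."""
        if self.times.size < 2:
            return []
        dt = np.diff(self.times)
        idx = np.flatnonzero(dt > GAP_FACTOR * self.sampling_interval)
        return [(float(self.times[i]), float(self.times[i + 1])) for i in idx]

    def to_frame(self) -> pd.DataFrame:
        """Recording as a DataFrame with a ``time_s`` column."""
        df = pd.DataFrame(self.potentials, columns=list(self.channel_labels))
        df.insert(0, "time_s", self.times)
        return df


@dataclass(frozen=True)
class ChannelStats:
    """Baseline (median) and variability (standard deviation) of one channel.

    Both are computed over the full unfiltered series: the median resists
    large-amplitude excursions, and the standard deviation quantifies
    fluctuation about it.  They anchor the spike-detection threshold
    ``baseline + k * sigma``.
    """

    baseline: float  # mV
    sigma: float  # mV

    def threshold(self, k: float) -> float:
        return self.baseline + k * self.sigma


@dataclass
class ValidationReport:
    """Report-only structural diagnostics of a recording."""

    n_channels: int
    n_samples: int
    duration: float
    gaps: list[tuple[float, float]] = field(default_factory=list)
    constant_channels: list[str] = field(default_factory=list)
    nan_runs: list[tuple[str, float, float]] = field(default_factory=list)
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def _parse_table(path: Path, dialect: str) -> pd.DataFrame:
    text = path.read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    try:
        # round_trip float parsing keeps write/read cycles bit-identical
        df = pd.read_csv(path, sep=sep, header=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pandas names the offending line
        raise ValueError(f"unparseable row in {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise ValueError(
            f"{path}: found {df.shape[1] - 1} channel column(s); at least 2 required"
        )
    return df


def read_recording(
    path: str | Path,
    dialect: str = "plain",
    *,
    unit: str = "mV",
    sampling_interval: float | None = None,
    spacing_cm: float = 2.0,
) -> Recording:
    """Read a delimited logger export into a :class:`Recording`.

    Parameters
    ----------
    path
        Comma- or tab-delimited text file with a header row; first column is
        time (dialect-dependent), remaining columns are channels.
    dialect
        ``"plain"`` (time already in seconds) or ``"timestamped"``
        (ISO-like timestamps, converted by time-delta to seconds).
    unit
        Source unit of the potential columns; coerced to mV on read.
    sampling_interval
        Nominal sample period in seconds.  Inferred from the median time step
        when omitted.

    Times are shifted so the first sample is at t = 0.  Non-monotone times,
    unparseable rows and fewer than two channel columns raise ``ValueError``.
    """
    path = Path(path)
    if dialect not in ("plain", "timestamped"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'plain' or 'timestamped'")
    if unit not in _UNIT_TO_MV:
        raise ValueError(f"unknown unit {unit!r}; use one of {sorted(_UNIT_TO_MV)}")
    df = _parse_table(path, dialect)

    tcol = df.iloc[:, 0]
    if dialect == "timestamped":
        stamps = pd.to_datetime(tcol, errors="raise")
        times = (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy(dtype=float)
    else:
        times = pd.to_numeric(tcol, errors="raise").to_numpy(dtype=float)
        times = times - times[0]

    bad = np.flatnonzero(np.diff(times) <= 0)
    if bad.size:
        # +3: header line, 1-based, and diff offset
        raise ValueError(
            f"{path}: non-monotone time at line {int(bad[0]) + 3} "
            f"(t={times[bad[0] + 1]:g} s follows t={times[bad[0]]:g} s)"
        )

    pots = df.iloc[:, 1:].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    pots = pots * _UNIT_TO_MV[unit]
    labels = tuple(str(c) for c in df.columns[1:])

    if sampling_interval is None:
        sampling_interval = float(np.median(np.diff(times))) if len(times) > 1 else 1.0

    return Recording(
        channel_labels=labels,
        times=times,
        potentials=pots,
        sampling_interval=sampling_interval,
        spacing_cm=spacing_cm,
    )


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write the canonical plain dialect (seconds + per-channel mV columns).

    Values are written with ``repr`` precision so that a read/write round
    trip reproduces times and potentials bit-identically.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(",".join(("time_s", *recording.channel_labels)) + "\n")
        for t, row in zip(recording.times, recording.potentials):
            fh.write(",".join(repr(float(v)) for v in (t, *row)) + "\n")


def compute_channel_stats(recording: Recording, channel: int) -> ChannelStats:
    """Baseline (median) and sigma (standard deviation) of one channel.

    Both statistics use the full unfiltered series; no detrending or
    windowing is applied, so they are invariant under sample reordering.
    """
    if not 0 <= channel < recording.n_channels:
        raise IndexError(f"channel {channel} out of range 0..{recording.n_channels - 1}")
    series = recording.channel(channel)
    if series.size == 0:
        raise ValueError("cannot compute statistics of an empty series")
    return ChannelStats(baseline=float(np.median(series)), sigma=float(np.std(series)))


def _nan_runs(times: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    runs = []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        runs.append((float(times[start]), float(times[stop - 1])))
    return runs


def validate_recording(recording: Recording) -> ValidationReport:
    """Structural diagnostics: gaps, constant channels, NaN runs.

    Report-only; never raises.  A gap is a time step exceeding
    ``GAP_FACTOR`` times the nominal sampling interval.
    """
    report = ValidationReport(
        n_channels=recording.n_channels,
        n_samples=recording.n_samples,
        duration=recording.duration,
        gaps=recording.gaps(),
    )
    for gap in report.gaps:
        report.issues.append(f"sampling gap between t={gap[0]:g} s and t={gap[1]:g} s")
    for i, label in enumerate(recording.channel_labels):
        series = recording.channel(i)
        finite = series[np.isfinite(series)]
        if finite.size and np.all(finite == finite[0]):
            report.constant_channels.append(label)
            report.issues.append(f"zero-variance channel {label!r}")
        nan_mask = ~np.isfinite(series)
        if nan_mask.any():
            for t0, t1 in _nan_runs(recording.times, nan_mask):
                report.nan_runs.append((label, t0, t1))
                report.issues.append(
                    f"non-finite values on channel {label!r} between t={t0:g} and t={t1:g} s"
                )
    return report
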