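"""Synthetic multichannel recordings with known ground truth.

The generator emulates the statistical structure of slow electrical
activity in fungal-colonised substrate so that every analysis stage can be
verified against known inputs:

* **Waveform** — each spike is a difference-of-exponentials kernel
  ``A * (exp(-t/tau_decay) - exp(-t/tau_rise))`` normalised to unit peak,
  giving the characteristic slow rise and longer relaxation.  Defaults
  tau_rise = 80 s, tau_decay = 320 s put the kernel's full width at half
  maximum near 430 s, the scale of observed median spike widths.
* **Point process** — onsets on the source channel follow a heavy-tailed
  lognormal renewal process (median 6.5e3 s, shape sigma = sqrt(ln 2) so
  CV = 1), with a burst mixture: each renewal event starts a burst with
  probability 0.08, appending 1–3 extra spikes at short intervals
  (mean 1.3e3 s, i.e. 20% of the ISI median target), so that roughly a
  quarter of spikes end up inside bursts under the 30%-of-median-ISI rule
  (chance pairs of the heavy-tailed renewal process count too).
* **Propagation** — channel c repeats the source onsets delayed by
  (c-1) * spacing_cm / velocity (in seconds) plus independent Gaussian
  jitter, so the configured velocity is recoverable from the delay–distance
  relation.  Amplitude is drawn once per event and shared across channels,
  mirroring a wave whose size is set at generation.
* **Trace** — events superpose additively on a baseline with optional
  linear drift and Gaussian sensor noise.  Overlapping excursions merge in
  the detector by construction; the generator does not prevent overlap.

All randomness flows from a single seed; identical config + seed gives a
bit-identical Recording and GroundTruth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .recording import Recording

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "spike_kernel",
    "kernel_peak_time",
    "kernel_width_above",
    "generate_onset_process",
    "propagate_onsets",
    "render_recording",
    "generate_recording",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic recording generator.

    Defaults reproduce the observed regime: 8 channels 2 cm apart sampled
    at 1 Hz, ISI median 6.5e3 s with CV ~ 1, ~25% of spikes in bursts of
    2–4, amplitudes with median 0.6 mV in [0.2, 1.4] mV, and propagation at
    0.7 cm/min (adjacent lag 171.4 s) with 20 s jitter.
    """

    n_channels: int = 8
    duration_s: float = 2e5
    sampling_interval: float = 1.0
    spacing_cm: float = 2.0
    velocity_cm_per_min: float | None = 0.7
    adjacent_lag_s: float | None = None  # overrides velocity when set
    lag_jitter_sd: float = 20.0
    propagation_failure_p: float = 0.0
    # renewal process
    isi_median_s: float = 6.5e3
    isi_sigma: float = 0.8325546111576977  # sqrt(ln 2): lognormal CV = 1
    burst_prob: float = 0.08
    burst_size_range: tuple[int, int] = (2, 4)
    within_burst_isi_s: float = 1.3e3
    # waveform
    tau_rise_s: float = 80.0
    tau_decay_s: float = 320.0
    amplitude_median_mv: float = 0.6
    amplitude_sigma: float = 0.35
    amplitude_range_mv: tuple[float, float] = (0.2, 1.4)
    # trace
    noise_sd_mv: float = 0.05
    baseline_mv: float = 0.2
    drift_mv: float = 0.1  # total linear drift over the full duration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_decay_s <= self.tau_rise_s:
            raise ValueError("tau_decay_s must exceed tau_rise_s")
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.adjacent_lag_s is None:
            if self.velocity_cm_per_min is None or self.velocity_cm_per_min <= 0:
                raise ValueError("velocity_cm_per_min must be positive "
                                 "(or set adjacent_lag_s explicitly)")
        elif self.adjacent_lag_s <= 0:
            raise ValueError("adjacent_lag_s must be positive")
        if not 0 <= self.propagation_failure_p < 1:
            raise ValueError("propagation_failure_p must lie in [0, 1)")
        lo, hi = self.amplitude_range_mv
        if not 0 < lo < hi:
            raise ValueError("amplitude_range_mv must satisfy 0 < lo < hi")

    @property
    def adjacent_lag(self) -> float:
        """Inter-channel lag in seconds implied by the configured velocity."""
        if self.adjacent_lag_s is not None:
            return self.adjacent_lag_s
        return 60.0 * self.spacing_cm / self.velocity_cm_per_min

    @property
    def true_velocity_cm_per_min(self) -> float:
        return 60.0 * self.spacing_cm / self.adjacent_lag

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.pop("schema", None)
        for key in ("burst_size_range", "amplitude_range_mv"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {"schema": 1, **asdict(self)}
        data["burst_size_range"] = list(self.burst_size_range)
        data["amplitude_range_mv"] = list(self.amplitude_range_mv)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass(frozen=True)
class GroundTruth:
    """Injected events underlying a rendered synthetic recording."""

    onsets: list[np.ndarray]  # per channel, seconds
    event_ids: list[np.ndarray]  # per channel, source-event index of each onset
    amplitudes: np.ndarray  # per source event, mV
    adjacent_lag_s: float
    velocity_cm_per_min: float
    kernel_width_fwhm_s: float
    n_dropped: int  # events clipped at the record edges and removed


def spike_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials waveform, normalised to unit peak, 0 for t<0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    raw = np.exp(-t[pos] / tau_decay) - np.exp(-t[pos] / tau_rise)
    t_peak = kernel_peak_time(tau_rise, tau_decay)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    out[pos] = raw / peak
    return out


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Closed-form argmax of the difference-of-exponentials kernel."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)) * np.log(tau_decay / tau_rise)


def kernel_width_above(level: float, tau_rise: float, tau_decay: float,
                       dt: float = 1.0) -> float:
    """Duration (s) the unit-peak kernel spends above ``level`` in (0, 1)."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    horizon = tau_decay * 12
    t = np.arange(0, horizon, dt)
    return float(np.sum(spike_kernel(t, tau_rise, tau_decay) >= level) * dt)


def generate_onset_process(
    config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw source-channel onsets: lognormal renewal with burst insertion.

    Each renewal event may start a burst (probability ``burst_prob``) whose
    extra members follow at exponentially jittered short intervals with
    mean ``within_burst_isi_s``.  A minimum gap of one waveform rise time
    is enforced between consecutive onsets.  Raises when the expected ISI
    exceeds the recording duration (no spikes could be placed).
    """
    mu = np.log(config.isi_median_s)
    mean_isi = np.exp(mu + config.isi_sigma**2 / 2)
    if config.duration_s <= 0:
        return np.array([])
    if mean_isi > config.duration_s:
        raise ValueError("infeasible config: expected ISI exceeds duration")
    min_gap = config.tau_rise_s
    onsets: list[float] = []
    t = float(rng.lognormal(mu, config.isi_sigma))
    while t < config.duration_s:
        onsets.append(t)
        if rng.random() < config.burst_prob:
            lo, hi = config.burst_size_range
            extra = int(rng.integers(lo, hi + 1)) - 1
            for _ in range(extra):
                gap = max(min_gap, float(rng.exponential(config.within_burst_isi_s)))
                t += gap
                if t >= config.duration_s:
                    break
                onsets.append(t)
        t += max(min_gap, float(rng.lognormal(mu, config.isi_sigma)))
    return np.array(onsets)


def propagate_onsets(
    source_onsets: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], list[np.ndarray], int]:
    """Delay source onsets down the array with per-event, per-channel jitter.

    Channel c (0-based) sees each source event at
    ``t + c * adjacent_lag + N(0, lag_jitter_sd^2)``; events may
    independently fail to propagate with ``propagation_failure_p``.  Onsets
    that land outside [0, duration) are dropped and counted.  Returns
    (onsets per channel, source-event ids per channel, n_dropped).
    """
    lag = config.adjacent_lag
    onsets_per_channel: list[np.ndarray] = []
    ids_per_channel: list[np.ndarray] = []
    dropped = 0
    n = source_onsets.size
    for c in range(config.n_channels):
        times = source_onsets + c * lag
        if config.lag_jitter_sd > 0 and c > 0:
            times = times + rng.normal(0.0, config.lag_jitter_sd, size=n)
        keep = (times >= 0) & (times < config.duration_s)
        if config.propagation_failure_p > 0 and c > 0:
            keep &= rng.random(n) >= config.propagation_failure_p
        dropped += int(n - keep.sum())
        order = np.argsort(times[keep], kind="stable")
        onsets_per_channel.append(times[keep][order])
        ids_per_channel.append(np.flatnonzero(keep)[order])
    return onsets_per_channel, ids_per_channel, dropped


def render_recording(
    onsets_per_channel: list[np.ndarray],
    config: SyntheticConfig,
    rng: np.random.Generator,
    event_ids: list[np.ndarray] | None = None,
    n_dropped: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Superpose amplitude-scaled kernels on baseline + drift + noise.

    One amplitude is drawn per source event (lognormal, median
    ``amplitude_median_mv``, truncated to ``amplitude_range_mv``) and shared
    by that event's appearance on every channel.  The result is a valid
    :class:`Recording` plus the ground truth needed for recovery tests.
    """
    n_samples = int(round(config.duration_s / config.sampling_interval))
    times = np.arange(n_samples) * config.sampling_interval
    if event_ids is None:
        event_ids = [np.arange(on.size) for on in onsets_per_channel]
    n_events = max((int(ids.max()) + 1 for ids in event_ids if ids.size), default=0)
    lo, hi = config.amplitude_range_mv
    amps = rng.lognormal(np.log(config.amplitude_median_mv),
                         config.amplitude_sigma, size=n_events)
    amps = np.clip(amps, lo, hi)

    kernel_span = int(np.ceil(12 * config.tau_decay_s / config.sampling_interval))
    kernel_t = np.arange(kernel_span) * config.sampling_interval
    kernel = spike_kernel(kernel_t, config.tau_rise_s, config.tau_decay_s)

    drift = (config.drift_mv * times / config.duration_s
             if config.duration_s > 0 else np.zeros_like(times))
    pots = np.empty((n_samples, config.n_channels))
    for c, (onsets, ids) in enumerate(zip(onsets_per_channel, event_ids)):
        trace = config.baseline_mv + drift.copy()
        if config.noise_sd_mv > 0:
            trace = trace + rng.normal(0.0, config.noise_sd_mv, size=n_samples)
        for onset, eid in zip(onsets, ids):
            start = int(round(onset / config.sampling_interval))
            stop = min(start + kernel_span, n_samples)
            if start >= n_samples:
                continue
            # sample the kernel at the exact offset from the (continuous) onset
            offs = times[start:stop] - onset
            trace[start:stop] += amps[eid] * spike_kernel(
                offs, config.tau_rise_s, config.tau_decay_s)
        pots[:, c] = trace

    recording = Recording(
        channel_labels=tuple(f"ch{c + 1}" for c in range(config.n_channels)),
        times=times,
        potentials=pots,
        sampling_interval=config.sampling_interval,
        spacing_cm=config.spacing_cm,
    )
    truth = GroundTruth(
        onsets=onsets_per_channel,
        event_ids=event_ids,
        amplitudes=amps,
        adjacent_lag_s=config.adjacent_lag,
        velocity_cm_per_min=config.true_velocity_cm_per_min,
        kernel_width_fwhm_s=kernel_width_above(
            0.5, config.tau_rise_s, config.tau_decay_s),
        n_dropped=n_dropped,
    )
    return recording, truth


def generate_recording(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[Recording, GroundTruth]:
    """End-to-end generation: onset process → propagation → rendered traces."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    source = generate_onset_process(config, rng)
    onsets, ids, dropped = propagate_onsets(source, config, rng)
    return render_recording(onsets, config, rng, event_ids=ids, n_dropped=dropped)
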