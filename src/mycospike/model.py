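"""Model/Results facade over the full spike-propagation analysis.

`SpikePropagation` is built from a :class:`~mycospike.recording.Recording`
(or a DataFrame) plus detection and association parameters; ``fit()`` runs
the deterministic pipeline — channel statistics, spike detection, train
statistics, lead–lag matrix, delay–distance fit — and returns a
`SpikePropagationResults` carrying the estimates, their uncertainty, and a
``summary()`` table.  Stochastic controls (surrogates) and plots hang off
the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from . import propagation as prop
from .detect import (DetectionParams, SpikeEvent, average_spike_shape,
                     detect_all_channels, events_to_frame, summarize_spikes)
from .recording import ChannelStats, Recording, compute_channel_stats
from .trains import SpikeTrain, isi_stats, isi_summary_table, trains_from_events

__all__ = ["SpikePropagation", "SpikePropagationResults"]


class SpikePropagation:
    """Spike detection and propagation model for a multichannel recording.

    Parameters
    ----------
    recording
        The multichannel differential-potential recording.
    detection
        Amplitude/duration spike criteria (default k = 2.0, w_min = 60 s).
    association
        Pairing window and matching rules (default dt_max = 300 s, scaled
        window, one-to-one nearest matching).
    """

    def __init__(
        self,
        recording: Recording,
        detection: DetectionParams | None = None,
        association: prop.AssociationParams | None = None,
    ) -> None:
        self.recording = recording
        self.detection = detection or DetectionParams()
        self.association = association or prop.AssociationParams()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_column: str = "time_s",
        spacing_cm: float = 2.0,
        **kwargs,
    ) -> "SpikePropagation":
        """Build the model from a seconds + per-channel-mV DataFrame."""
        times = df[time_column].to_numpy(dtype=float)
        channels = [c for c in df.columns if c != time_column]
        rec = Recording(
            channel_labels=tuple(channels),
            times=times - times[0],
            potentials=df[channels].to_numpy(dtype=float),
            sampling_interval=float(np.median(np.diff(times))) if len(times) > 1 else 1.0,
            spacing_cm=spacing_cm,
        )
        return cls(rec, **kwargs)

    def fit(self) -> "SpikePropagationResults":
        """Run the full deterministic pipeline and package the results."""
        rec = self.recording
        channel_stats = [compute_channel_stats(rec, c) for c in range(rec.n_channels)]
        events = detect_all_channels(rec, self.detection)
        trains = trains_from_events(events, rec.duration)
        matrix = prop.lead_lag_matrix(trains, self.association)
        separation = prop.delay_vs_separation(matrix, rec.spacing_cm)
        try:
            velocity = prop.fit_velocity(separation)
        except ValueError:
            velocity = None
        return SpikePropagationResults(
            model=self,
            channel_stats=channel_stats,
            events=events,
            trains=trains,
            delay_matrix=matrix,
            separation_delays=separation,
            velocity=velocity,
        )


@dataclass
class SpikePropagationResults:
    """Fitted pipeline output: spikes, trains, delays, velocity."""

    model: SpikePropagation
    channel_stats: list[ChannelStats]
    events: list[list[SpikeEvent]]
    trains: list[SpikeTrain]
    delay_matrix: prop.DelayMatrix
    separation_delays: list[prop.SeparationDelay]
    velocity: prop.VelocityEstimate | None

    # -- derived views -------------------------------------------------
    @property
    def all_events(self) -> list[SpikeEvent]:
        return [e for ch in self.events for e in ch]

    @property
    def n_spikes(self) -> int:
        return len(self.all_events)

    def spike_table(self) -> pd.DataFrame:
        return events_to_frame(self.all_events)

    def spike_summary(self) -> pd.DataFrame:
        return summarize_spikes(self.all_events)

    def isi_table(self) -> pd.DataFrame:
        return isi_summary_table(self.trains)

    def pooled_adjacent_median(self) -> float:
        adj = self.delay_matrix.adjacent_delays()
        return float(np.median(adj)) if adj.size else np.nan

    def average_shape(self, window: tuple[float, float] = (-60.0, 1200.0)):
        return average_spike_shape(self.model.recording, self.all_events, window)

    # -- stochastic controls -------------------------------------------
    def surrogates(
        self, n_surrogates: int = 100, seed: int | None = None,
        mode: str = "redraw",
    ) -> prop.SurrogateSummary:
        """Count-preserving timing-randomisation null (see `surrogate_control`)."""
        _, summary = prop.surrogate_control(
            self.trains, n_surrogates, self.model.association, seed=seed, mode=mode
        )
        return summary

    def sensitivity(self, k_values: Sequence[float] = (1.5, 2.0, 2.5)) -> pd.DataFrame:
        """Full-pipeline rerun per detection threshold multiplier."""
        return prop.threshold_sensitivity(
            self.model.recording, k_values, self.model.detection,
            self.model.association,
        )

    # -- presentation ---------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary of the fitted pipeline."""
        rec = self.model.recording
        widths = self.spike_summary()
        pooled = isi_stats(np.concatenate(
            [np.diff(tr.onsets) for tr in self.trains]
        ) if any(tr.n_spikes > 1 for tr in self.trains) else np.array([]))
        info = [
            ("Channels", f"{rec.n_channels}"),
            ("Duration (s)", f"{rec.duration:.0f}"),
            ("Detection", f"k={self.model.detection.k:g}, "
                          f"w_min={self.model.detection.w_min:g} s"),
            ("Association", f"dt_max={self.model.association.dt_max:g} s, "
                            f"{self.model.association.window_policy} window, "
                            f"{self.model.association.matching}"),
            ("Spikes detected", f"{self.n_spikes}"),
            ("Median width (s)", f"{widths.loc['width_s', 'median']:.1f}"),
            ("Median amplitude (mV)", f"{widths.loc['amplitude_mV', 'median']:.3f}"),
            ("Pooled median ISI (s)", f"{pooled.median:.0f}"),
            ("Pooled ISI CV", f"{pooled.cv:.2f}"),
            ("Adjacent median delay (s)", f"{self.pooled_adjacent_median():.1f}"),
        ]
        if self.velocity is not None and self.velocity.velocity_cm_per_min is not None:
            v = self.velocity
            info += [
                ("Theil-Sen slope (s/cm)",
                 f"{v.slope:.2f}  [{v.slope_ci[0]:.2f}, {v.slope_ci[1]:.2f}]"),
                ("Velocity (cm/min)", f"{v.velocity_cm_per_min:.3f}"),
                ("Velocity (cm/h)", f"{v.velocity_cm_per_h:.1f}"),
            ]
        else:
            info.append(("Velocity", "undefined (no positive delay-distance slope)"))
        table = SimpleTable(
            [[v] for _, v in info],
            headers=["value"],
            stubs=[k for k, _ in info],
            title="Spike propagation analysis",
        )
        return str(table)

    # -- plotting -------------------------------------------------------
    def plot_raster(self, ax=None, window: tuple[float, float] | None = None):
        """Onset raster, one row per channel."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t1 = self.model.recording.duration
        win = window or (0.0, t1 if t1 > 0 else 1.0)
        for tr in self.trains:
            on = tr.onsets[(tr.onsets >= win[0]) & (tr.onsets < win[1])]
            ax.vlines(on, tr.channel + 0.6, tr.channel + 1.4)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("channel")
        ax.set_yticks(range(1, len(self.trains) + 1))
        return ax

    def plot_delay_vs_distance(self, ax=None):
        """Median delay against physical separation with the robust fit line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = [p for p in self.separation_delays if p.n_pairs > 0]
        x = [p.distance_cm for p in pts]
        y = [p.median_delay for p in pts]
        ax.plot(x, y, "o", label="median delay")
        if self.velocity is not None:
            xs = np.linspace(0, max(x), 50)
            ax.plot(xs, self.velocity.intercept + self.velocity.slope * xs,
                    "-", label=f"Theil-Sen ({self.velocity.slope:.1f} s/cm)")
        ax.set_xlabel("distance (cm)")
        ax.set_ylabel("median delay (s)")
        ax.legend()
        return ax

    def plot_average_shape(self, ax=None, window=(-60.0, 1200.0)):
        """Mean onset-aligned normalised waveform with IQR band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        shape = self.average_shape(window)
        ax.plot(shape.time_grid, shape.mean_waveform, label="mean")
        ax.fill_between(shape.time_grid, shape.q25, shape.q75, alpha=0.3,
                        label="IQR")
        ax.set_xlabel("time from onset (s)")
        ax.set_ylabel("normalised potential")
        ax.legend()
        return ax
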