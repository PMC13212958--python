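# mycospike

Analysis of slow electrical spike propagation in fungal-colonised
substrate, recorded with a linear array of differential electrode channels.

Fungal mycelium supports spontaneous electrical activity that is slow by
neural standards: millivolt-scale excursions lasting 10²–10³ s, recurring
at intervals of minutes to hours. Given a multichannel recording from an
ordered array (C channels, one sample per second, adjacent channel centres
2 cm apart), `mycospike` answers three questions:

1. **What are the spikes?** Per channel, baseline V_b = median of the full
   raw series and variability σ = its standard deviation; a spike is a
   maximal run with V(t) > V_b + kσ (k = 2.0) lasting ≥ W_min = 60 s, with
   width, amplitude A = max(V − V_b), onset-aligned average waveform.
2. **How are they organised in time?** Each channel as a point process of
   onsets: ISI statistics and CV = σ_ISI/μ_ISI, and bursts — runs of ≥ 2
   spikes whose ISIs are each below 30% of the channel's median ISI.
3. **Do they propagate?** Onsets on channel pairs are associated within a
   temporal window (Δt_max = 300 s per separation step) and matched one to
   one; the median signed delay per ordered pair forms a lead–lag matrix,
   pooled by separation s into median delay vs distance L(s) = 2s cm, and a
   Theil–Sen fit of delay on distance gives the propagation velocity
   v = 60/slope cm/min. Count-preserving onset randomisation provides the
   null, and a threshold sweep (k ∈ {1.5, 2.0, 2.5}) the robustness check.

A synthetic-recording generator with ground truth (asymmetric
difference-of-exponentials spike waveforms, heavy-tailed lognormal ISIs
with a burst mixture, directional propagation with jitter, baseline drift
and noise) makes every stage verifiable without access to a real
recording. It is first-class, tested code, and defines the conditions
under which the pipeline's recovery properties are demonstrated.

## Worked example

```python
from mycospike import SpikePropagation, SyntheticConfig
from mycospike.simulate import generate_recording

recording, truth = generate_recording(SyntheticConfig(), seed=1)
results = SpikePropagation(recording).fit()
print(results.summary())
```

```
                        Spike propagation analysis
=========================================================================
                                               value
-------------------------------------------------------------------------
Channels                                                                8
Duration (s)                                                       199999
Detection                                                 k=2, w_min=60 s
Association               dt_max=300 s, scaled window, one_to_one_nearest
Spikes detected                                                       210
Median width (s)                                                    311.0
Median amplitude (mV)                                               0.690
Pooled median ISI (s)                                                5459
Pooled ISI CV                                                        1.09
Adjacent median delay (s)                                           169.0
Theil-Sen slope (s/cm)                              84.40  [83.50, 85.25]
Velocity (cm/min)                                                   0.711
Velocity (cm/h)                                                      42.7
-------------------------------------------------------------------------
```

The recording was generated with a true propagation velocity of
0.7 cm/min (adjacent-channel lag 171.4 s): 210 spikes are detected across
the 8 channels, their pooled inter-spike intervals are heavy-tailed with
CV ≈ 1 (irregular, Poisson-like rather than periodic), the median delay
between adjacent channels is 169 s, and the robust delay-versus-distance
fit recovers 0.711 cm/min — within 2% of the configured value. The
equivalent one-line conversion for a single adjacent-channel delay:

```python
>>> from mycospike import velocity_from_adjacent
>>> velocity_from_adjacent(180.0, spacing_cm=2.0)
(0.6666666666666666, 40.0)   # cm/min, cm/h
```

`results.surrogates(100, seed=1)` re-randomises onsets per channel
(counts preserved) and shows the delay structure collapsing to zero-centred
medians with the monotone lead–lag ordering destroyed;
`results.sensitivity()` reruns everything at k = 1.5/2.0/2.5.

A command-line interface wraps the same pipeline for batch use:

```sh
mycospike simulate --outdir sim
mycospike analyze --input sim/recording.csv --dialect plain --outdir out
mycospike surrogate --input sim/recording.csv --surrogates 100 --seed 1
mycospike sensitivity --input sim/recording.csv --k-values 1.5,2.0,2.5
```

`analyze` accepts a `timestamped` dialect (ISO-like stamps, converted to
seconds by time-delta) for raw logger exports, writes per-stage delimited
tables plus a `summary.json` whose provenance block (parameters, seed,
input digest, version) suffices to regenerate the report bit-identically.

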