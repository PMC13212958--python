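# Methods

This note documents the models and procedures implemented in `mycospike`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Signal model and spike definition

The input is a multichannel extracellular differential-potential recording
from a linear electrode array in fungal-colonised substrate: C ≥ 2 channels,
one sample per second, millivolt scale, channel order corresponding to
physical position with adjacent channel centres `spacing_cm` apart (2 cm by
default). The electrical events of interest are slow — tens of seconds to
tens of minutes — so the pipeline is strictly time-domain and applies no
detrending, smoothing or frequency-domain filtering anywhere; doing so would
distort exactly the slow dynamics being measured.

Per channel, the baseline V_b is the **median** of the full raw series
(robust to the large excursions being detected) and the variability σ is the
**standard deviation** of the full raw series (population form, ddof = 0; at
the relevant sample counts of ~10⁵–10⁶ the distinction from ddof = 1 is far
below any threshold that matters). A spike is a maximal run of consecutive
samples with

    V(t) > V_b + k·σ,        k = 2.0 by default,

kept only if the run lasts at least W_min = 60 s. Width is the number of
supra-threshold samples times the sampling interval — a 60-sample run at
1 Hz is exactly 60 s, which resolves the one-sample ambiguity in defining a
duration from a closed interval — and amplitude is max(V − V_b) over the
run. There is no upper duration limit. A sampling gap (step > 1.5× the
nominal interval) terminates any open run, so events never bridge recording
discontinuities. Only positive-going excursions are detected by default; a
mirrored negative-polarity mode exists (`DetectionParams(negative_polarity=True)`)
but is off, since only the positive condition defines the standard analysis.

Tunables: `k` (unitless; 2.0 balances false threshold crossings of baseline
noise against missed low spikes; 1.5 and 2.5 are the conventional
sensitivity bounds), `w_min` (s; 60 s excludes fast transients that are not
the slow events of interest).

## Spike morphology

The average spike shape aligns each event at onset, subtracts the channel
baseline, divides by the event amplitude (so each contributor peaks at 1
inside its run), and reports the pointwise mean and 25th/75th percentiles on
a common grid. The default window, −60 s to +1200 s around onset, covers the
observed width range (~10² to 1.2×10³ s). Events whose window would cross a
record edge are dropped and counted rather than zero-padded.

## Point-process statistics

Each channel's detected onsets form a spike train. ISIs are onset
differences; their mean, median, sd and coefficient of variation CV = sd/mean
are reported per channel and pooled (the pooled CV uses pooled intervals).
A `heavy_tailed` flag records median < mean. Bursts follow the
fraction-of-median rule: a burst is a maximal run of ≥ 2 spikes whose
separating ISIs are each **strictly below 30% of that channel's own median
ISI** computed over the full recording (never a pooled median); both
endpoints of each qualifying interval are burst members. Trains with fewer
than 3 onsets return no bursts rather than an error, since a median over
≥ 2 intervals is required. No stationarity correction or windowing is
applied anywhere.

## Lead–lag association and delays

For an ordered channel pair (c, d), onsets are associated when they fall
within a temporal window. Two window policies exist:

* `fixed` — the window is Δt_max (default 300 s) for every pair; this is
  the literal printed rule.
* `scaled` (default) — the window for separation s = |d − c| is s·Δt_max.
  A fixed 300 s window cannot contain delays that themselves grow by
  ~180 s per channel step, so it would truncate exactly the large-separation
  delays the distance fit needs; scaling the window with the expected delay
  reconciles this while `fixed` remains available for comparison.

Matching is `one_to_one_nearest` by default: candidate pairs are sorted by
|delay| (ties: smaller lead onset, then smaller lag onset) and accepted
greedily with each spike used at most once. This prevents one spike from
being counted into many pairs; an `all_pairs` mode keeps every candidate
for comparison. The signed delay is lag onset minus lead onset, so positive
delays mean the lower-indexed channel leads.

The lead–lag matrix holds the median signed delay per ordered pair (NaN
when no pairs exist; 0 on the diagonal). Delay-versus-distance pools the
raw matched delays of all ordered pairs at each separation s, takes their
median, and converts separation to distance L(s) = spacing_cm·s.

## Velocity estimation

Median delay against distance is fitted with a **Theil–Sen** estimator
(median of pairwise slopes, free intercept, 95% slope CI from
`scipy.stats.theilslopes`). Theil–Sen was chosen because the fit has at
most C−1 points, each itself a median of a possibly small pool, and a
single noisy large-separation median should not leverage the slope; any
reasonable robust line would serve. A positive slope b (s/cm) gives the
effective velocity 60/b cm/min; a non-positive slope leaves the velocity
explicitly undefined rather than reporting a negative speed. Per-separation
velocities L(s)/median(s) are reported alongside as a constancy check, and
`velocity_from_adjacent` provides the one-line conversion
60·spacing/median_delay used in the worked example (180 s, 2 cm →
0.667 cm/min = 40 cm/h).

## Surrogate control

The propagation null randomises timing while preserving per-channel spike
counts. Literally permuting a channel's own onset *set* is the identity
map, so "permutation" is implemented as:

* `redraw` (default) — each channel's n onsets are redrawn uniformly over
  [0, duration] and sorted;
* `isi_shuffle` — the channel's own ISIs are permuted and re-accumulated
  from the first onset, preserving the interval distribution as well.

Per surrogate the full matrix is recomputed; reported are the median of
pooled adjacent delays, an asymmetry index (signed excess of positive
adjacent delays), and whether the monotone lead–lag ordering (all adjacent
medians defined and positive) survived. 100 seeded surrogates are the
default. Under the null, adjacent medians centre on zero and the monotone
ordering occurs at roughly the 2⁻⁷ chance level for 8 channels.

## Threshold sensitivity

`threshold_sensitivity` reruns detection → trains → matrix → velocity per
k (default {1.5, 2.0, 2.5}) and tabulates spike counts, the pooled adjacent
median delay and its sign, and the velocity. On spike-shaped signals counts
are monotone non-increasing in k; note this is not a theorem for arbitrary
signals, since a higher threshold can split one long excursion of a
pathological waveform into several qualifying runs.

## Synthetic recordings

The generator emulates the statistical regime of the real recordings so
every stage has ground truth; its defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| channels / spacing / rate | 8, 2 cm, 1 Hz | array geometry |
| duration | 2×10⁵ s | ~200 spikes pooled across channels |
| waveform | diff-of-exponentials, τ_rise 80 s, τ_decay 320 s | slow rise, longer relaxation; FWHM ≈ 430 s, the observed median width scale |
| amplitudes | lognormal, median 0.6 mV, clipped to [0.2, 1.4] mV | observed amplitude range; drawn once per event, shared across channels |
| ISI model | lognormal renewal, median 6.5×10³ s, σ = √ln2 (CV = 1) | observed heavy-tailed pooled ISI statistics |
| bursts | start prob. 0.08, sizes 2–4, within-burst gap mean 1.3×10³ s | see below |
| propagation | 0.7 cm/min (adjacent lag 171.4 s), jitter sd 20 s | observed velocity; ~12% relative jitter |
| trace | baseline 0.2 mV, linear drift 0.1 mV over the record, noise sd 0.05 mV | drift/noise small relative to spikes, as in the recordings |

The burst start probability was calibrated once against the burst *rule*:
under the 30%-of-median threshold, chance short intervals of the
heavy-tailed renewal process alone contribute ~14% burst membership, so a
start probability of 0.08 brings the expected detected burst fraction to
~0.24, the centre of the observed 15–35% range. The within-burst gap mean
of 1.3×10³ s (20% of the ISI median) keeps within-burst intervals below the
burst threshold while staying far enough apart that consecutive ~430 s-wide
spikes do not merge into one supra-threshold run. Amplitude and width are
drawn independently — no amplitude–width correlation is imposed.

What the generator does **not** emulate: electrode drift nonlinearity,
common-mode artefacts shared across channels, propagation failure is off by
default (available via `propagation_failure_p`), 2-D network branching (the
array is linear), and any mechanistic ionic dynamics. Passing recovery
tests therefore demonstrates correctness of the analysis pipeline on
signals with the stated statistical structure, not validity of any
biophysical model of the substrate.

Determinism: all randomness flows from one `numpy` Generator seeded from
the config (or an explicit seed); identical config + seed reproduces the
Recording and GroundTruth bit-for-bit.

## Numerical and edge-case choices

* Uniform-grid times are stored as float seconds with t = 0 at the first
  sample; parsing uses round-trip float precision so a write/read cycle is
  bit-identical.
* Empty inputs return explicit empty summaries (n = 0, NaN statistics)
  from statistics functions; constructive operations (average shape,
  velocity fit) raise `ValueError` when their preconditions fail.
* Zero-variance channels make the detection threshold undefined and raise;
  the multichannel driver skips such channels with an empty event list.
* In the uniform-redraw surrogate, exact ties (measure-zero) are broken by
  an additive 1e-9 s ramp to keep onsets strictly increasing.
* The greedy matcher's tie rule makes swapped lead/lag matchings exact
  negations for generic (tie-free) delays; contrived equal-|delay| ties
  across distinct spike pairs could in principle select differently in the
  two directions.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run entirely on synthetic data:
five to ten default-condition recordings (2×10⁵ samples × 8 channels),
100-surrogate null ensembles, and a 2×10⁶ s single-channel onset process
for the burst fraction (a few hundred events are needed before the
fraction concentrates within the quoted band). These sizes make every
statistic stable at the quoted tolerances while keeping a full run in the
order of seconds.

## Known limitations

* The timestamped dialect accepts anything `pandas.to_datetime` parses; a
  vendor export with locale-dependent formats should be converted to the
  plain dialect first.
* The burst fraction of a single default-length recording (~25 spikes per
  channel) has a sampling sd of ~0.11; per-recording burst fractions are
  only indicative at that length.
* One-to-one greedy matching is order-optimal for well-separated trains but
  is not a global assignment; with spike rates approaching the window
  width, a Hungarian-style matcher would differ.
* The velocity CI reflects only the delay-versus-distance fit, not the
  uncertainty of each pooled median.
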