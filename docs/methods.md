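# Methods

This note documents the models, statistics and numerical choices behind
`bfphys`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Task and session model

A session is a sequence of trials on one clock. Each trial draws a cue
identity (Cue 1 with probability `p_cue1`, default 0.5 — the cue mix is a
free design parameter), a foreperiod from an exponential distribution of
mean 2 s truncated to [1, 4] s by rejection (the truncated-exponential
family keeps temporal expectation of the cue low while concentrating mass
early; the untruncated mean is a package choice, exposed as
`foreperiod_mean`), a 1 s cue, a uniform 200–400 ms reinforcement delay,
and an outcome from the cue's contingency triplet (defaults 0.80/0.10/0.10
and 0.25/0.65/0.10 for reward/punishment/omission). Omission trials record
the scheduled delivery time as `outcome_time` — the moment at which nothing
arrived — so that outcome-aligned analyses of expectation are possible.

Trials use independent random sub-streams keyed by `(seed, trial_index)`,
so enlarging `n_trials` reproduces the earlier trials bit-for-bit. Trial
restarts on foreperiod licks are not simulated; foreperiods are lick-free
by construction, which leaves every downstream statistic unchanged while
removing a behavioral feedback loop from the generator.

### Lick model

Licking is an inhomogeneous Poisson process. Between cue onset and
reinforcement the rate ramps linearly from a base rate (1 Hz) to
`base + learning × p_reward(cue)` (learning default 6 Hz per unit reward
probability), which produces both the differential anticipatory lick rate
and the faster reaction times to the reward-predicting cue with two
parameters. After reward a consummatory bout follows (6 Hz for 1.5 s).
The model reproduces the qualitative structure of real lick rasters —
cue-locked ramping, cue-value dependence, consummatory bursts — but not
lick rhythmicity (~7 Hz periodicity), satiety drift, or foreperiod licks.

### Spike-train model

Units are inhomogeneous Poisson. The k-th event of a kind opens a response
window `[latency + jitter·N(0,1), +response_duration]` in which the rate is
`baseline × gain × adaptation^(k−1)`; outside windows the rate is the
baseline. Simulation is by thinning from a homogeneous envelope, so the
rate function is honored exactly; on the rare overlap of two windows the
later-opened window's rate applies. A `burstiness` fraction of spikes is
expanded into 2–4 spike bursts with 3–8 ms intra-burst intervals, after
which the train is sorted and deduplicated at 0.1 ms resolution. Real
extracellular data additionally show refractory dynamics, rate
nonstationarity and spike-sorting contamination; passing tests on this
generator therefore validate the estimators' logic and calibration, not
robustness to sorting artifacts.

### Photostimulation model

Tagging epochs hold 25 (configurable 20–30) blocks of 2 s of 1 ms pulses
at 20 Hz separated by 3 s pauses, preceded by 130 s of pulse-free baseline.
A tagged unit fires per pulse with probability `reliability` at
`latency ± jitter` on top of baseline Poisson spiking. The 130 s baseline
is sized so the latency test can tile 100 baseline histograms of 130
windows of 10 ms each (see below).

### Photometry model

The latent activity is a sum of event kernels (difference of exponentials,
rise 0.1 s, decay 1.0 s — GCaMP6s-like kinetics) scaled by event gains and
adaptation. The calcium channel is
`f465 = B(t)(1 + gain·a(t)) + motion + noise` with an exponentially
bleaching baseline `B(t)` (τ = 600 s); the isosbestic channel is
`f405 = c·B(t) + share·motion + noise`. The default isosbestic scale is
`c = 1` and `share = 1`: an additive artifact is removable by a single
affine fit only when it enters both channels on the same scale, which is
the regime the isosbestic method assumes (in hardware, differing channel
gains are calibrated out). Both `c` and `share` are configurable to study
imperfect coupling. Signals are generated at the demodulated level
(default 1 kHz); carrier modulation and lock-in demodulation are hardware
concerns outside the model.

## Tagging statistics

The latency test builds first-spike latency histograms over half-open
10 ms windows at 1 ms resolution with an explicit terminal "no spike" bin,
so silent windows contribute mass rather than being dropped. One histogram
comes from the (pulse-onset-aligned) test windows; N = 100 come from
windows tiled over the pulse-free baseline epochs.

Calibration rests on exchangeability: all N+1 histograms aggregate the same
number m of windows. m is the number of pulses when the baseline can tile
N·m windows, otherwise the pulses are subsampled (seeded) to the largest
supportable m. For each histogram the median Jensen–Shannon divergence to
all others is computed, and

    p = (1 + #{baseline medians ≥ test median}) / (N + 1).

Under a stationary null the N+1 median statistics are exchangeable, so p is
uniform on {1/(N+1), …, 1} and P(p < 0.01) = 1/101 ≈ 0.0099 with the
default N; ties are counted conservatively. The reported divergence is the
median test-vs-baseline JSD in bits; latency and jitter are the median and
median absolute deviation of post-pulse first-spike latencies. The final
tagging decision additionally requires a light-evoked vs spontaneous
waveform correlation of at least 0.84 when a waveform is available
(decisions without waveforms are flagged). The test is deliberately
specified by its calibration property rather than by any particular legacy
implementation; the rank scheme above is this package's definition.

## Spike-train statistics

- **PETHs** pool counts across trials and divide by `n_events × binsize`.
  Smoothing uses a Gaussian kernel: SD 0.02 s for spikes (narrow enough to
  resolve fast phasic responses; the appropriate width for spike data is a
  package choice), 0.1 s for licks and photometry.
- **Z-scoring** uses the mean and SD (ddof = 1) of the baseline bins
  (default −1–0 s). Zero-variance baselines are flagged `degenerate` with
  z set to 0 and should be excluded from population averages — never
  silently divided.
- **Response classification** compares per-trial baseline and test rates
  (counts divided by window length, so equal-length windows reduce to
  counts) with one-sided Mann–Whitney U tests in both directions at
  α = 0.001. The baseline window is anchored to the cue of the same trial
  even when the test window follows the outcome. The 0–0.5 s test window
  is used for all event types.
- **Session halves** split events at the median event index (first half
  gets the extra event); clock-time splits would confound with trial-rate
  drift. Peaks are read from the smoothed PETH within 0–0.5 s.
- **Autocorrelograms** count ordered spike pairs per 0.5 ms lag bin up to
  the maximum lag, excluding zero-lag self pairs. Surrogate normalization
  uses 100 ISI-shuffled surrogates with per-lag z-scoring; ISI shuffling
  preserves the rate and ISI marginal while destroying temporal order,
  which is the property the normalization needs. The burst index uses the
  max over 0–10 ms against the mean over 180–200 ms, normalized by the
  larger, and is defined 0 when both vanish. Note the max-over-bins term
  is upward-biased for short recordings; the BI > 0.3 bursting convention
  presupposes session-length trains (tens of minutes).
- **Burst segmentation** is the deterministic left-to-right scan: a burst
  opens on an ISI < 10 ms and extends while ISIs stay < 15 ms.
- **Clustering** computes principal components of the unit × bin matrix of
  z-scored two-cue PETHs and runs K-means (k = 5, 50 restarts, seeded) on
  the first 3 scores. Clusters are renumbered by descending tagged
  fraction (ties by size). Duplicate centers (degenerate geometry) are
  flagged rather than hidden.
- **Unit quality**: squared Mahalanobis distances of noise spikes under
  the cluster covariance give the isolation distance (n_cluster-th closest
  noise spike; NaN when there are fewer noise spikes than cluster spikes)
  and `L-ratio = Σ(1 − χ²_d CDF(D²))/n_cluster`; gates at ID > 20 and
  L < 0.15. Singular covariances raise with guidance to reduce dimensions.
- **Duplicates**: candidate pairs share a tetrode and lie within 200 µm
  dorso-ventrally; duplicates require waveform Pearson r ≥ 0.95 and ACG
  cosine similarity ≥ 0.9 (conservative thresholds chosen inside the
  correlation range observed for genuinely identical units), and connected
  components are counted once.

## Photometry processing

Both Butterworth filters are order 4 (unspecified in common protocols;
order 4 gives ~80 dB/decade without ringing) and applied
forward-backward, so they are zero-phase — transient peak latencies are
preserved to within a sample. The operation order is: low-pass both raw
channels → isosbestic fit on the full recording → dF/F → high-pass the
dF/F. The high-pass targets the slow baseline decrease and is read as
acting on dF/F; a switch (`highpass_before_dff`) applies it to the raw
channels instead for comparison. A moving-window fit is deliberately not
the default: the full-recording fit keeps the correction linear and
auditable. Recordings shorter than 3 high-pass periods skip the filter
with a warning. Event alignment drops events whose window leaves the
recording (with a count), smooths per-trial snippets (100 ms Gaussian),
averages, and z-scores by the trial-averaged pre-cue baseline; the
per-trial matrix is returned for single-trial displays.

## Behavioral statistics

The auROC at each 10 ms bin is the Mann–Whitney `U/(n_A n_B)` with ties
half-weighted. The per-session series entering the group comparison is the
smoothed (Cue 1 − Cue 2) lick-rate difference over 0–1.1 s — the
differential-licking reading; raw per-cue rates can be passed instead.
Significance per bin comes from 200 random relabelings of the pooled
sessions, two-sided on |auROC − 0.5|, with the attainable floor
1/201 ≈ 0.005 reported explicitly. No correction across time bins is
applied; contiguous significant spans are reported instead, matching
field practice for time-course ROC displays.

## Problem sizes used in validation

The test suite validates calibration at: 10,000 trials per cue for outcome
contingencies (3 binomial SEs); 1,000 random trains for burst-index bounds
and the segmentation oracle; 1,000 null and 100 driven replicates of the
25-block tagging protocol for the latency test (null rate within
[0.005, 0.02] at p < 0.01, power ≥ 95%); 1,000 null and 200 driven units
for the response classifier (false-call rate ≤ 2α + 3 MC SE, power ≥ 95%
for a 4× gain over 50 trials); 125-trial photometry sessions at 1 kHz with
60 event-shuffle nulls for artifact rejection; 200 random instances (≤ 50
samples per group) for auROC-vs-brute-force equality; and a 100-unit
5-archetype population for clustering recovery (ARI ≥ 0.9).

## Known limitations

- The generators are Poisson at heart: no refractoriness beyond the 0.1 ms
  resolution floor, no oscillatory or state-dependent rate structure.
- The latency test assumes stationary baseline firing; slow drift across
  the baseline epoch would inflate baseline divergences and make the test
  conservative, not anticonservative.
- The isosbestic correction removes exactly the artifact component that is
  affine between channels; wavelength-dependent artifacts degrade it
  gracefully (configurable via `motion_share_405` and `isosbestic_scale`).
- The z-scored photometry peak saturates as response amplitude grows,
  because response tails bleed into subsequent pre-cue baselines and
  inflate the baseline SD proportionally; the per-trial dF/F amplitude is
  the better recovery measure at large gains.
- Clustering on 3 principal components assumes response archetypes are
  linearly separable at that rank; k and the rank are parameters, not
  discoveries.
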