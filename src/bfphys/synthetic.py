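"""Generators for probabilistic Pavlovian conditioning sessions.

The simulated task is the head-fixed two-cue design: after a lick-free
inter-trial period a 1 s pure-tone cue is played following a 1-4 s
truncated-exponential foreperiod; reinforcement (water reward, air-puff
punishment, or omission) arrives 200-400 ms after cue offset. Cue 1 predicts
likely reward (80/10/10 % reward/punishment/omission), Cue 2 likely punishment
(25/65/10 %). Licking is an inhomogeneous Poisson process whose anticipatory
rate ramps between cue and outcome in proportion to the cue's reward
probability (a "learning" gain), with a consummatory bout after reward.

Spike trains are inhomogeneous Poisson with event-locked rate windows,
optional per-presentation adaptation and ISI-defined bursting; photometry is a
two-channel (calcium-dependent + isosbestic) fluorescence pair with shared
bleaching, shared motion artifact and event-kernel neural signal. Every
generator is deterministic given its seed, and session trials use per-trial
sub-streams so extending a session never perturbs earlier trials.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .core import SpikeTrain

__all__ = [
    "SessionConfig",
    "ResponseProfile",
    "PhotometryConfig",
    "PhotometryRecording",
    "TaggingEpoch",
    "generate_session",
    "generate_spike_train",
    "generate_tagging_epoch",
    "generate_photometry",
    "event_times",
    "TRIAL_COLUMNS",
]

OUTCOMES = ("reward", "punishment", "omission")
TRIAL_COLUMNS = ("trial", "cue_id", "cue_onset", "outcome", "outcome_time", "foreperiod")

_MIN_SPIKE_SEP = 1e-4  # s; spike trains are unique at 0.1 ms resolution


@dataclass
class SessionConfig:
    """Trial structure and lick-model parameters of one conditioning session.

    Defaults reproduce the task: contingencies (0.80, 0.10, 0.10) for Cue 1
    and (0.25, 0.65, 0.10) for Cue 2; 1-4 s foreperiod drawn from an
    exponential of (untruncated) mean 2 s by rejection; 1 s cue; 200-400 ms
    reinforcement delay; 1.5 s of lick-free time before the next trial.
    ``learning`` scales how strongly the anticipatory lick-rate ramp depends
    on the cue's reward probability (0 = naive animal).
    """

    n_trials: int = 200
    p_cue1: float = 0.5
    contingencies: Mapping[int, Tuple[float, float, float]] = field(
        default_factory=lambda: {1: (0.80, 0.10, 0.10), 2: (0.25, 0.65, 0.10)}
    )
    foreperiod_range: Tuple[float, float] = (1.0, 4.0)
    foreperiod_mean: float = 2.0
    delay_range: Tuple[float, float] = (0.2, 0.4)
    cue_duration: float = 1.0
    iti_quiet: float = 1.5
    lick_base: float = 1.0          # Hz, cue-independent anticipatory floor
    learning: float = 6.0           # Hz per unit reward probability at outcome time
    consummatory_rate: float = 6.0  # Hz after reward
    consummatory_duration: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if not 0.0 <= self.p_cue1 <= 1.0:
            raise ValueError("p_cue1 must be a probability")
        for cue, triplet in self.contingencies.items():
            arr = np.asarray(triplet, dtype=float)
            if arr.shape != (3,) or np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"contingency triplet for cue {cue} is not a probability triplet")
            if abs(arr.sum() - 1.0) > 1e-12:
                raise ValueError(f"contingency triplet for cue {cue} must sum to 1")
        lo, hi = self.foreperiod_range
        if lo < 0 or lo >= hi:
            raise ValueError("foreperiod_range must satisfy 0 <= min < max")
        if self.foreperiod_mean <= 0:
            raise ValueError("foreperiod_mean must be positive")
        dlo, dhi = self.delay_range
        if dlo < 0 or dlo > dhi:
            raise ValueError("delay_range must satisfy 0 <= min <= max")
        if self.cue_duration < 0 or self.iti_quiet < 0:
            raise ValueError("durations must be non-negative")
        if self.lick_base < 0 or self.learning < 0 or self.consummatory_rate < 0:
            raise ValueError("lick rates must be non-negative")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


@dataclass
class ResponseProfile:
    """Event-locked firing (or fluorescence) response of one simulated unit.

    ``gains`` maps event kinds ("cue1", "cue2", "cue", "reward",
    "punishment", "omission") to multiplicative rate factors applied within
    ``[latency, latency + response_duration]`` after each event; the k-th
    presentation of a kind is scaled by ``adaptation**(k-1)``. ``burstiness``
    is the fraction of spikes replaced by short 2-4 spike bursts with
    intra-burst ISIs of 3-8 ms.
    """

    baseline_rate: float = 5.0
    gains: Mapping[str, float] = field(default_factory=dict)
    latency: float = 0.03
    jitter: float = 0.005
    response_duration: float = 0.25
    burstiness: float = 0.0
    adaptation: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        for kind, g in self.gains.items():
            if g < 0:
                raise ValueError(f"gain for {kind!r} must be non-negative")
        if self.jitter < 0 or self.response_duration < 0:
            raise ValueError("jitter and response_duration must be non-negative")
        if not 0.0 <= self.burstiness <= 1.0:
            raise ValueError("burstiness must lie in [0, 1]")
        if not 0.0 < self.adaptation <= 1.0:
            raise ValueError("adaptation must lie in (0, 1]")


@dataclass
class PhotometryConfig:
    """Parameters of the simulated demodulated two-channel fluorescence pair.

    The artifact-removal logic of the isosbestic fit assumes the motion
    artifact couples into both channels on the same additive scale, which is
    why the isosbestic baseline defaults to the same magnitude as the
    calcium-dependent one (``isosbestic_scale = 1``).
    """

    fs: float = 1000.0              # Hz, demodulated sampling rate
    bleach_tau: float = 600.0       # s, photobleaching time constant
    kernel_rise: float = 0.1        # s, indicator rise time constant
    kernel_decay: float = 1.0       # s, indicator decay time constant
    motion_amp: float = 1.0         # fluorescence units (SD of artifact)
    motion_share_405: float = 1.0   # coupling of artifact into the 405 channel
    noise_sd: float = 0.05          # fluorescence units, per-channel white noise
    gain: float = 0.05              # fractional 465 modulation per unit activity
    baseline_f: float = 100.0       # fluorescence units at t=0 (465 channel)
    isosbestic_scale: float = 1.0   # 405 baseline relative to 465 baseline
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 40.0:
            raise ValueError("fs must exceed 40 Hz (twice the 20 Hz low-pass cutoff)")
        if self.kernel_rise >= self.kernel_decay:
            raise ValueError("kernel_rise must be smaller than kernel_decay")
        for name in ("bleach_tau", "motion_amp", "noise_sd", "gain", "baseline_f", "isosbestic_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.motion_share_405 < 0:
            raise ValueError("motion_share_405 must be non-negative")


@dataclass
class PhotometryRecording:
    """Uniformly sampled calcium-dependent and isosbestic channel pair."""

    t: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        if not (self.t.shape == self.f465.shape == self.f405.shape):
            raise ValueError("t, f465 and f405 must have equal lengths")
        if self.fs <= 40.0:
            raise ValueError("fs must exceed 40 Hz")


@dataclass
class TaggingEpoch:
    """Photostimulation pulse train plus the spiking recorded around it."""

    pulse_times: np.ndarray
    spikes: SpikeTrain
    baseline_epochs: Tuple[Tuple[float, float], ...]
    duration: float


def _trial_rng(seed: int, index: int) -> np.random.Generator:
    # independent, reproducible sub-stream per trial index
    return np.random.default_rng([seed, index])


def _truncated_exponential(rng: np.random.Generator, mean: float, lo: float, hi: float) -> float:
    while True:
        x = rng.exponential(mean)
        if lo <= x <= hi:
            return float(x)


def _ramp_poisson(
    rng: np.random.Generator, t0: float, t1: float, r0: float, r1: float
) -> np.ndarray:
    """Inhomogeneous Poisson times on [t0, t1) with a linear rate ramp r0 -> r1."""
    span = t1 - t0
    rmax = max(r0, r1)
    if span <= 0 or rmax <= 0:
        return np.empty(0)
    n = rng.poisson(rmax * span)
    ts = np.sort(rng.uniform(0.0, span, n))
    rate = r0 + (r1 - r0) * ts / span
    keep = rng.random(n) < rate / rmax
    return t0 + ts[keep]


def generate_session(config: SessionConfig) -> Tuple[pd.DataFrame, np.ndarray]:
    """Simulate one session: a trial table and the session lick train.

    Returns
    -------
    trials : pandas.DataFrame
        Columns ``trial, cue_id, cue_onset, outcome, outcome_time,
        foreperiod``; ``outcome_time`` is the (scheduled) reinforcement time,
        also recorded for omission trials as the moment nothing was delivered.
    licks : ndarray
        Sorted lick times in seconds on the session clock.
    """
    rows = []
    licks: list[np.ndarray] = []
    cues = sorted(config.contingencies)
    t = config.iti_quiet
    for i in range(config.n_trials):
        rng = _trial_rng(config.seed, i)
        if len(cues) == 1:
            cue = cues[0]
            rng.random()  # keep the stream layout identical across cue mixes
        else:
            cue = 1 if rng.random() < config.p_cue1 else 2
        fp = _truncated_exponential(
            rng, config.foreperiod_mean, *config.foreperiod_range
        )
        cue_onset = t + fp
        outcome = OUTCOMES[rng.choice(3, p=np.asarray(config.contingencies[cue], float))]
        delay = rng.uniform(*config.delay_range)
        outcome_time = cue_onset + config.cue_duration + delay
        p_reward = float(config.contingencies[cue][0])
        anticipatory = _ramp_poisson(
            rng,
            cue_onset,
            outcome_time,
            config.lick_base,
            config.lick_base + config.learning * p_reward,
        )
        licks.append(anticipatory)
        t = outcome_time
        if outcome == "reward" and config.consummatory_rate > 0:
            n = rng.poisson(config.consummatory_rate * config.consummatory_duration)
            bout = outcome_time + np.sort(
                rng.uniform(0.0, config.consummatory_duration, n)
            )
            licks.append(bout)
            t = outcome_time + config.consummatory_duration
        t += config.iti_quiet
        rows.append((i, cue, cue_onset, outcome, outcome_time, fp))
    trials = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    trials = trials.astype(
        {"trial": int, "cue_id": int, "cue_onset": float, "outcome_time": float, "foreperiod": float}
    )
    all_licks = np.sort(np.concatenate(licks)) if licks else np.empty(0)
    return trials, all_licks


def event_times(trials: pd.DataFrame, kind: str) -> np.ndarray:
    """Event times of one kind from a trial table.

    ``kind`` is one of ``cue`` (all cue onsets), ``cue1``/``cue2`` (per cue
    identity), or ``reward``/``punishment``/``omission`` (outcome times).
    """
    if kind == "cue":
        return trials["cue_onset"].to_numpy(float)
    if kind in ("cue1", "cue2"):
        cid = int(kind[-1])
        return trials.loc[trials["cue_id"] == cid, "cue_onset"].to_numpy(float)
    if kind in OUTCOMES:
        return trials.loc[trials["outcome"] == kind, "outcome_time"].to_numpy(float)
    raise ValueError(f"unknown event kind {kind!r}")


def _dedupe(times: np.ndarray, min_sep: float = _MIN_SPIKE_SEP) -> np.ndarray:
    times = np.sort(times)
    if times.size == 0 or np.all(np.diff(times) >= min_sep):
        return times
    keep = np.empty(times.size, dtype=bool)
    keep[0] = True
    last = times[0]
    for i in range(1, times.size):
        if times[i] - last >= min_sep:
            keep[i] = True
            last = times[i]
        else:
            keep[i] = False
    return times[keep]


def generate_spike_train(
    trials: pd.DataFrame,
    profile: ResponseProfile,
    seed: int = 0,
    duration: Optional[float] = None,
    unit_id: str = "sim",
) -> SpikeTrain:
    """Simulate an event-locked inhomogeneous Poisson unit.

    Within ``[latency, latency + response_duration]`` after the k-th event of
    a kind the rate is ``baseline * gain * adaptation**(k-1)`` (the most
    recently opened response window wins on the rare overlaps); elsewhere it
    is ``baseline``. Spikes are then thinned from a homogeneous envelope,
    a ``burstiness`` fraction is expanded into short bursts, and the train is
    made strictly sorted with 0.1 ms resolution.
    """
    rng = np.random.default_rng(seed)
    if duration is None:
        if len(trials) == 0:
            raise ValueError("duration is required for an empty trial table")
        duration = float(trials["outcome_time"].max()) + 5.0
    starts, ends, rates = [], [], []
    for kind, gain in profile.gains.items():
        ev = event_times(trials, kind)
        for k, e in enumerate(ev):
            onset = e + profile.latency + profile.jitter * rng.standard_normal()
            starts.append(onset)
            ends.append(onset + profile.response_duration)
            rates.append(profile.baseline_rate * gain * profile.adaptation ** k)
    if starts:
        order = np.argsort(starts)
        starts = np.asarray(starts)[order]
        ends = np.asarray(ends)[order]
        rates = np.asarray(rates)[order]
        lam_max = max(profile.baseline_rate, float(rates.max()))
    else:
        starts = ends = rates = np.empty(0)
        lam_max = profile.baseline_rate

    n = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n))
    if starts.size:
        idx = np.searchsorted(starts, cand, side="right") - 1
        in_win = (idx >= 0) & (cand < ends[np.clip(idx, 0, None)])
        lam = np.where(in_win, rates[np.clip(idx, 0, None)], profile.baseline_rate)
    else:
        lam = np.full(cand.shape, profile.baseline_rate)
    spikes = cand[rng.random(n) < lam / lam_max]

    if profile.burstiness > 0 and spikes.size:
        seeds = spikes[rng.random(spikes.size) < profile.burstiness]
        extras = []
        for s in seeds:
            n_extra = rng.integers(1, 4)  # bursts of 2-4 spikes total
            isis = rng.uniform(0.003, 0.008, n_extra)
            extras.append(s + np.cumsum(isis))
        if extras:
            spikes = np.concatenate([spikes] + extras)
    return SpikeTrain(times=_dedupe(spikes), unit_id=unit_id)


def generate_tagging_epoch(
    tagged: bool,
    latency: float = 0.003,
    jitter: float = 0.0005,
    reliability: float = 0.9,
    baseline_rate: float = 10.0,
    seed: int = 0,
    n_blocks: int = 25,
    pulse_rate: float = 20.0,
    block_duration: float = 2.0,
    pause: float = 3.0,
    baseline_duration: float = 130.0,
) -> TaggingEpoch:
    """Simulate a photostimulation epoch: 1 ms pulse trains plus spiking.

    Pulses come in ``n_blocks`` blocks of ``block_duration`` seconds at
    ``pulse_rate`` Hz separated by ``pause`` seconds, preceded by
    ``baseline_duration`` seconds of pulse-free recording. If ``tagged``,
    each pulse evokes a spike with probability ``reliability`` at
    ``latency +/- jitter``; otherwise spiking is baseline Poisson.
    """
    if not 0.0 <= reliability <= 1.0:
        raise ValueError("reliability must lie in [0, 1]")
    if baseline_rate < 0 or latency < 0 or jitter < 0:
        raise ValueError("rates, latency and jitter must be non-negative")
    if n_blocks < 1 or pulse_rate <= 0 or block_duration <= 0:
        raise ValueError("invalid pulse-train geometry")
    rng = np.random.default_rng(seed)
    per_block = int(round(block_duration * pulse_rate))
    pulses = np.concatenate(
        [
            baseline_duration + b * (block_duration + pause) + np.arange(per_block) / pulse_rate
            for b in range(n_blocks)
        ]
    )
    duration = baseline_duration + n_blocks * (block_duration + pause) + 2.0
    n = rng.poisson(baseline_rate * duration)
    spikes = rng.uniform(0.0, duration, n)
    if tagged and reliability > 0:
        hit = rng.random(pulses.size) < reliability
        evoked = pulses[hit] + latency + jitter * rng.standard_normal(int(hit.sum()))
        evoked = np.maximum(evoked, pulses[hit] + 2e-4)
        spikes = np.concatenate([spikes, evoked])
    return TaggingEpoch(
        pulse_times=pulses,
        spikes=SpikeTrain(times=_dedupe(spikes), unit_id="tag-sim"),
        baseline_epochs=((0.0, float(baseline_duration)),),
        duration=float(duration),
    )


def generate_photometry(
    trials: pd.DataFrame,
    profile: ResponseProfile,
    pconfig: PhotometryConfig,
    duration: Optional[float] = None,
) -> PhotometryRecording:
    """Simulate a demodulated two-channel fluorescence recording.

    Latent activity is a sum of event-locked difference-of-exponential
    kernels scaled by the profile's gains (with per-presentation
    adaptation); it modulates the bleaching 465 nm baseline multiplicatively
    through ``pconfig.gain``. A band-limited motion artifact and white noise
    are shared/added per the config.
    """
    fs = pconfig.fs
    if duration is None:
        if len(trials) == 0:
            raise ValueError("duration is required for an empty trial table")
        duration = float(trials["outcome_time"].max()) + 6.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(pconfig.seed)

    # event kernel, peak-normalized to 1
    tk = np.arange(0.0, 6.0 * pconfig.kernel_decay, 1.0 / fs)
    kern = np.exp(-tk / pconfig.kernel_decay) - np.exp(-tk / pconfig.kernel_rise)
    kern /= kern.max()

    activity = np.zeros(n)
    for kind, gain in profile.gains.items():
        for k, e in enumerate(event_times(trials, kind)):
            i0 = int(round(e * fs))
            if i0 >= n:
                continue
            seg = min(kern.size, n - i0)
            activity[i0 : i0 + seg] += gain * profile.adaptation ** k * kern[:seg]

    bleach = np.exp(-t / pconfig.bleach_tau) if pconfig.bleach_tau > 0 else np.ones(n)
    b465 = pconfig.baseline_f * bleach
    b405 = pconfig.isosbestic_scale * pconfig.baseline_f * bleach

    if pconfig.motion_amp > 0:
        sos = butter(2, 3.0, btype="low", fs=fs, output="sos")
        motion = sosfiltfilt(sos, rng.standard_normal(n))
        motion *= pconfig.motion_amp / motion.std()
    else:
        motion = np.zeros(n)

    noise465 = pconfig.noise_sd * rng.standard_normal(n) if pconfig.noise_sd > 0 else 0.0
    noise405 = pconfig.noise_sd * rng.standard_normal(n) if pconfig.noise_sd > 0 else 0.0
    f465 = b465 * (1.0 + pconfig.gain * activity) + motion + noise465
    f405 = b405 + pconfig.motion_share_405 * motion + noise405
    return PhotometryRecording(t=t, f465=f465, f405=f405, fs=fs)
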