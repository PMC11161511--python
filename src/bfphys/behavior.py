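"""Lick-based behavioral readouts.

Lick PETHs, anticipatory lick rates in the pre-reinforcement window
(0.6-1.1 s from cue onset), reaction times to cue onset, and the auROC
time-course with a label-permutation significance test used to compare
groups of sessions on their differential anticipatory licking.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import rankdata

from .core import Peth, point_process_peth, window_counts
from .synthetic import event_times

__all__ = [
    "AurocTimecourse",
    "lick_peth",
    "anticipatory_rate",
    "reaction_time",
    "auroc",
    "auroc_timecourse",
    "session_lick_difference",
    "significant_spans",
]

ANTICIPATORY_WINDOW = (0.6, 1.1)  # s from cue onset, pre-reinforcement


def lick_peth(
    licks: np.ndarray,
    events: Sequence[float],
    window: Tuple[float, float] = (-2.0, 3.0),
    binsize: float = 0.01,
    kernel_sd: float = 0.1,
) -> Peth:
    """Trial-averaged lick rate around events, 100 ms Gaussian smoothed."""
    return point_process_peth(np.asarray(licks, float), events, window, binsize, kernel_sd)


def anticipatory_rate(
    licks: np.ndarray,
    cue_onset: float | Sequence[float],
    window: Tuple[float, float] = ANTICIPATORY_WINDOW,
) -> float | np.ndarray:
    """Mean lick rate (Hz) in a window from cue onset; scalar or per-trial."""
    length = window[1] - window[0]
    if length <= 0:
        raise ValueError("window must have positive length")
    scalar = np.isscalar(cue_onset)
    onsets = np.atleast_1d(np.asarray(cue_onset, dtype=float))
    rates = window_counts(np.asarray(licks, float), onsets, window) / length
    return float(rates[0]) if scalar else rates


def reaction_time(
    licks: np.ndarray,
    cue_onset: float | Sequence[float],
    max_wait: float = 2.0,
) -> float | np.ndarray:
    """Latency of the first lick after cue onset; NaN marks censored trials.

    Trials without a lick within ``max_wait`` are censored (NaN) and should
    be excluded from averages.
    """
    if max_wait <= 0:
        raise ValueError("max_wait must be positive")
    licks = np.asarray(licks, dtype=float)
    scalar = np.isscalar(cue_onset)
    onsets = np.atleast_1d(np.asarray(cue_onset, dtype=float))
    idx = np.searchsorted(licks, onsets, side="right")
    rt = np.full(onsets.size, np.nan)
    has = idx < licks.size
    cand = np.where(has, licks[np.minimum(idx, licks.size - 1)] - onsets, np.inf)
    ok = cand <= max_wait
    rt[ok] = cand[ok]
    return float(rt[0]) if scalar else rt


def auroc(a: np.ndarray, b: np.ndarray) -> float:
    """P(random a > random b), ties counted half (Mann-Whitney U / (nA*nB))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def _auroc_columns(x: np.ndarray, n_a: int) -> np.ndarray:
    """Per-column auROC of the first n_a rows vs the rest."""
    ranks = rankdata(x, axis=0)
    n_b = x.shape[0] - n_a
    u = ranks[:n_a].sum(axis=0) - n_a * (n_a + 1) / 2.0
    return u / (n_a * n_b)


@dataclass
class AurocTimecourse:
    """Per-bin auROC of group A vs group B with permutation p-values."""

    bin_centers: np.ndarray          # s from cue onset
    auroc: np.ndarray
    p: np.ndarray                    # two-sided permutation p per bin
    n_resamples: int

    @property
    def p_floor(self) -> float:
        """Smallest attainable p given the number of resamplings."""
        return 1.0 / (self.n_resamples + 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.bin_centers, "auroc": self.auroc, "p": self.p}
        )


def auroc_timecourse(
    group_a: np.ndarray,
    group_b: np.ndarray,
    t_max: float = 1.1,
    step: float = 0.01,
    n_resamples: int = 200,
    seed: int = 0,
    bin_centers: Optional[np.ndarray] = None,
) -> AurocTimecourse:
    """auROC of two groups of per-session series at every time bin.

    ``group_a`` and ``group_b`` are session x bin matrices sampled every
    ``step`` seconds over [0, t_max] (each row is typically a session's
    smoothed Cue 1 - Cue 2 anticipatory lick-rate difference; raw rates work
    too). Significance per bin comes from ``n_resamples`` random relabelings
    of the pooled sessions, two-sided on |auROC - 0.5|, with the attainable
    floor 1/(n_resamples+1).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 sessions")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must be sampled on the same time bins")
    n_bins = a.shape[1]
    if bin_centers is None:
        bin_centers = np.arange(n_bins) * step
        if n_bins != int(round(t_max / step)) + 1:
            # caller supplied matrices on their own grid; keep the index grid
            pass
    pooled = np.vstack([a, b])
    obs = _auroc_columns(pooled, a.shape[0])
    rng = np.random.default_rng(seed)
    obs_dev = np.abs(obs - 0.5)
    exceed = np.zeros(n_bins)
    for _ in range(n_resamples):
        perm = rng.permutation(pooled.shape[0])
        dev = np.abs(_auroc_columns(pooled[perm], a.shape[0]) - 0.5)
        exceed += dev >= obs_dev - 1e-12
    p = (1.0 + exceed) / (n_resamples + 1.0)
    return AurocTimecourse(
        bin_centers=np.asarray(bin_centers, dtype=float),
        auroc=obs,
        p=p,
        n_resamples=n_resamples,
    )


def session_lick_difference(
    licks: np.ndarray,
    trials: pd.DataFrame,
    t_max: float = 1.1,
    step: float = 0.01,
    kernel_sd: float = 0.1,
) -> np.ndarray:
    """Smoothed Cue 1 - Cue 2 lick-rate difference over [0, t_max].

    The per-session quantity entering the group auROC comparison: lick PETHs
    aligned to each cue's onsets, sampled every ``step`` seconds, subtracted.
    """
    out = []
    for kind in ("cue1", "cue2"):
        ev = event_times(trials, kind)
        p = lick_peth(licks, ev, window=(0.0, t_max + step), binsize=step, kernel_sd=kernel_sd)
        out.append(p.rate[: int(round(t_max / step)) + 1])
    return out[0] - out[1]


def significant_spans(tc: AurocTimecourse, alpha: float = 0.05) -> list[tuple[float, float]]:
    """Contiguous time spans with p below alpha (no multiplicity correction)."""
    sig = tc.p < alpha
    spans = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = tc.bin_centers[i]
        elif not s and start is not None:
            spans.append((float(start), float(tc.bin_centers[i - 1])))
            start = None
    if start is not None:
        spans.append((float(start), float(tc.bin_centers[-1])))
    return spans
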