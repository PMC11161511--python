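"""Fiber-photometry processing: isosbestic-corrected dF/F and event alignment.

The chain is: zero-phase Butterworth low-pass (20 Hz) on both raw channels,
ordinary least-squares fit of the calcium-dependent 465 nm channel on the
isosbestic 405 nm channel, dF/F in percent,

    dff = (f465 - f405_fitted) / f405_fitted * 100,

a zero-phase 0.2 Hz high-pass on the dF/F to remove the slow bleaching
baseline, and finally event alignment with 100 ms Gaussian smoothing and
pre-cue baseline z-scoring. Because the isosbestic channel is calcium-
independent, the fitted 405 signal captures motion and autofluorescence and
the division removes them.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, sosfiltfilt
from scipy.stats import linregress

from .core import Peth
from .synthetic import PhotometryRecording

__all__ = [
    "DffTrace",
    "IsosbesticFit",
    "AlignedDff",
    "lowpass",
    "fit_isosbestic",
    "compute_dff",
    "highpass",
    "align_average",
    "process",
]


@dataclass
class IsosbesticFit:
    """Least-squares alignment of the 405 channel to the 465 channel."""

    slope: float
    intercept: float
    f405_fitted: np.ndarray


@dataclass
class DffTrace:
    """Isosbestic-corrected fractional fluorescence in percent."""

    t: np.ndarray
    dff: np.ndarray                  # percent
    fs: float
    fit_slope: float
    fit_intercept: float
    filters: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.t.shape != self.dff.shape:
            raise ValueError("t and dff must have equal lengths")


def _butter_sos(cutoff: float, fs: float, btype: str, order: int):
    if cutoff <= 0 or cutoff >= fs / 2:
        raise ValueError(f"{btype} cutoff must lie in (0, fs/2)")
    return butter(order, cutoff, btype=btype, fs=fs, output="sos")


def lowpass(
    recording: PhotometryRecording, cutoff: float = 20.0, order: int = 4
) -> PhotometryRecording:
    """Zero-phase Butterworth low-pass of both raw channels (DC gain 1)."""
    sos = _butter_sos(cutoff, recording.fs, "low", order)
    return PhotometryRecording(
        t=recording.t,
        f465=sosfiltfilt(sos, recording.f465),
        f405=sosfiltfilt(sos, recording.f405),
        fs=recording.fs,
    )


def fit_isosbestic(
    f465: np.ndarray, f405: np.ndarray, allow_intercept_only: bool = False
) -> IsosbesticFit:
    """OLS fit of f465 on f405; returns slope, intercept and the fitted 405.

    A constant 405 channel has no usable variance; by default this raises,
    or with ``allow_intercept_only`` falls back to fitting the mean of f465.
    """
    f465 = np.asarray(f465, dtype=float)
    f405 = np.asarray(f405, dtype=float)
    if f465.shape != f405.shape:
        raise ValueError("channels must have equal lengths")
    if np.ptp(f405) == 0.0 or np.var(f405) == 0.0:
        if allow_intercept_only:
            return IsosbesticFit(0.0, float(f465.mean()), np.full_like(f465, f465.mean()))
        raise ValueError("isosbestic channel is constant; cannot fit (set allow_intercept_only)")
    res = linregress(f405, f465)
    fitted = res.slope * f405 + res.intercept
    return IsosbesticFit(float(res.slope), float(res.intercept), fitted)


def compute_dff(
    f465: np.ndarray,
    f405_fitted: np.ndarray,
    t: Optional[np.ndarray] = None,
    fs: float = 0.0,
    fit: Optional[IsosbesticFit] = None,
) -> DffTrace:
    """Elementwise dF/F in percent against the fitted isosbestic channel."""
    f465 = np.asarray(f465, dtype=float)
    f405_fitted = np.asarray(f405_fitted, dtype=float)
    if np.any(f405_fitted <= 0):
        raise ValueError(
            "fitted isosbestic values must be positive; the fit failed or the signal bleached through"
        )
    dff = (f465 - f405_fitted) / f405_fitted * 100.0
    if t is None:
        t = np.arange(dff.size) / fs if fs > 0 else np.arange(dff.size, dtype=float)
    return DffTrace(
        t=t,
        dff=dff,
        fs=fs,
        fit_slope=fit.slope if fit else float("nan"),
        fit_intercept=fit.intercept if fit else float("nan"),
        filters=[],
    )


def highpass(trace: DffTrace, cutoff: float = 0.2, order: int = 4) -> DffTrace:
    """Zero-phase high-pass of the dF/F to remove slow baseline decay.

    Recordings shorter than 3 cutoff periods cannot support the filter; the
    trace is returned unchanged with a warning in that case.
    """
    duration = trace.t[-1] - trace.t[0] if trace.t.size > 1 else 0.0
    if duration < 3.0 / cutoff:
        warnings.warn("recording shorter than 3/cutoff; high-pass skipped")
        return trace
    sos = _butter_sos(cutoff, trace.fs, "high", order)
    return DffTrace(
        t=trace.t,
        dff=sosfiltfilt(sos, trace.dff),
        fs=trace.fs,
        fit_slope=trace.fit_slope,
        fit_intercept=trace.fit_intercept,
        filters=trace.filters + [f"highpass_butter{order}_{cutoff}Hz"],
    )


@dataclass
class AlignedDff:
    """Event-aligned dF/F: z-scored average plus the per-trial matrix."""

    peth: Peth                       # z-units
    trials: np.ndarray               # trial x sample smoothed dff (percent)
    n_dropped: int                   # events too close to the recording edges


def align_average(
    trace: DffTrace,
    events: Sequence[float],
    window: Tuple[float, float] = (-2.0, 4.0),
    kernel_sd: float = 0.1,
    baseline: Tuple[float, float] = (-1.0, 0.0),
    baseline_events: Optional[Sequence[float]] = None,
) -> AlignedDff:
    """Align dF/F to events, smooth, z-score by the pre-cue baseline, average.

    ``baseline_events`` defaults to the aligning events; pass cue onsets when
    aligning to reinforcement so the baseline is the second before the cue of
    the same trial. Events whose window leaves the recording are dropped and
    counted. A zero-variance baseline flags the PETH degenerate (z = 0).
    """
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("events must be non-empty")
    base_ev = events if baseline_events is None else np.asarray(baseline_events, float)
    if base_ev.size != events.size:
        raise ValueError("baseline_events must match events one-to-one")
    fs = trace.fs
    t0 = trace.t[0]
    n = trace.dff.size
    n_pre = int(round(-window[0] * fs))
    n_post = int(round(window[1] * fs))
    nb_pre = int(round(-baseline[0] * fs))
    nb_post = int(round(baseline[1] * fs))

    snippets, base_snips = [], []
    dropped = 0
    for e, be in zip(events, base_ev):
        i = int(round((e - t0) * fs))
        ib = int(round((be - t0) * fs))
        if i - n_pre < 0 or i + n_post > n or ib - nb_pre < 0 or ib + nb_post > n:
            dropped += 1
            continue
        snippets.append(trace.dff[i - n_pre : i + n_post])
        base_snips.append(trace.dff[ib - nb_pre : ib + nb_post])
    if not snippets:
        raise ValueError("all events fall too close to the recording edges")
    sigma = kernel_sd * fs
    mat = np.asarray(snippets)
    if sigma > 0:
        mat = gaussian_filter1d(mat, sigma, axis=1, mode="nearest")
    bmat = np.asarray(base_snips)
    if sigma > 0 and bmat.shape[1] > 0:
        bmat = gaussian_filter1d(bmat, sigma, axis=1, mode="nearest")
    avg = mat.mean(axis=0)
    base_avg = bmat.mean(axis=0)
    mu = float(base_avg.mean())
    sd = float(base_avg.std(ddof=1)) if base_avg.size > 1 else 0.0
    centers = (np.arange(n_pre + n_post) - n_pre + 0.5) / fs
    if sd <= 1e-12:
        peth = Peth(
            bin_centers=centers,
            rate=np.zeros_like(avg),
            n_events=mat.shape[0],
            binsize=1.0 / fs,
            smoothing_sd=kernel_sd,
            baseline_window=tuple(baseline),
            zscored=True,
            degenerate=True,
        )
    else:
        peth = Peth(
            bin_centers=centers,
            rate=(avg - mu) / sd,
            n_events=mat.shape[0],
            binsize=1.0 / fs,
            smoothing_sd=kernel_sd,
            baseline_window=tuple(baseline),
            zscored=True,
        )
    return AlignedDff(peth=peth, trials=mat, n_dropped=dropped)


def process(
    recording: PhotometryRecording,
    lowpass_hz: float = 20.0,
    highpass_hz: float = 0.2,
    order: int = 4,
    highpass_before_dff: bool = False,
) -> DffTrace:
    """Full preprocessing chain: low-pass, isosbestic fit, dF/F, high-pass.

    ``highpass_before_dff`` switches the 0.2 Hz high-pass to act on both raw
    channels instead of the dF/F (off by default; the bleaching baseline is
    read as a property of the dF/F).
    """
    rec = lowpass(recording, lowpass_hz, order)
    if highpass_before_dff:
        sos = _butter_sos(highpass_hz, rec.fs, "high", order)
        # keep the channel means so the fit and the division stay well-posed
        f465 = sosfiltfilt(sos, rec.f465) + rec.f465.mean()
        f405 = sosfiltfilt(sos, rec.f405) + rec.f405.mean()
        rec = PhotometryRecording(t=rec.t, f465=f465, f405=f405, fs=rec.fs)
    fit = fit_isosbestic(rec.f465, rec.f405)
    trace = compute_dff(rec.f465, fit.f405_fitted, t=rec.t, fs=rec.fs, fit=fit)
    trace.filters.append(f"lowpass_butter{order}_{lowpass_hz}Hz")
    if not highpass_before_dff:
        trace = highpass(trace, highpass_hz, order)
    return trace
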