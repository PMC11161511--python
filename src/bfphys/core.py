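"""Shared containers and event-alignment primitives.

Times are seconds on a single session clock throughout the package; peri-event
quantities are seconds relative to the aligning event. Rates are Hz unless a
:class:`Peth` is z-scored, in which case they are in baseline-SD units.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SpikeTrain",
    "Peth",
    "event_relative_times",
    "point_process_peth",
    "window_counts",
]


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit, with optional waveform and geometry.

    Parameters
    ----------
    times : array of float
        Spike times in seconds, strictly increasing.
    unit_id : str
        Identifier used in reports and HDF5 group names.
    waveform : array, optional
        Mean spike waveform (samples, or channels x samples).
    depth_um : float, optional
        Dorso-ventral recording depth in micrometers.
    tetrode : int, optional
        Tetrode the unit was recorded on.
    """

    times: np.ndarray
    unit_id: str = "u0"
    waveform: Optional[np.ndarray] = None
    depth_um: Optional[float] = None
    tetrode: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.waveform is not None:
            self.waveform = np.asarray(self.waveform, dtype=float)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isi(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.times)


@dataclass
class Peth:
    """Binned, optionally smoothed / z-scored event-aligned rate series."""

    bin_centers: np.ndarray          # s relative to the aligning event
    rate: np.ndarray                 # Hz, or z-units if ``zscored``
    n_events: int
    binsize: float
    smoothing_sd: float = 0.0        # s; 0 means unsmoothed
    baseline_window: Optional[Tuple[float, float]] = None
    zscored: bool = False
    degenerate: bool = False         # zero-variance baseline; z set to 0

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.bin_centers.shape != self.rate.shape:
            raise ValueError("bin_centers and rate must have equal shapes")

    def copy_with(self, **kwargs) -> "Peth":
        return replace(self, **kwargs)

    def peak(self, window: Optional[Tuple[float, float]] = None) -> float:
        """Maximum rate, optionally restricted to a relative-time window."""
        if window is None:
            return float(np.max(self.rate))
        mask = (self.bin_centers >= window[0]) & (self.bin_centers <= window[1])
        if not np.any(mask):
            raise ValueError("peak window does not overlap the PETH support")
        return float(np.max(self.rate[mask]))


def event_relative_times(
    times: np.ndarray, events: Sequence[float], window: Tuple[float, float]
) -> np.ndarray:
    """Pool point-event times relative to each aligning event.

    Returns the concatenated relative times falling inside ``window``
    (half-open on the right) across all events.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    lo = np.searchsorted(times, events + window[0], side="left")
    hi = np.searchsorted(times, events + window[1], side="left")
    return np.concatenate(
        [times[a:b] - e for a, b, e in zip(lo, hi, events)]
        or [np.empty(0)]
    )


def point_process_peth(
    times: np.ndarray,
    events: Sequence[float],
    window: Tuple[float, float],
    binsize: float,
    kernel_sd: float = 0.0,
) -> Peth:
    """Trial-averaged rate of a point process around events.

    Counts are pooled across events, converted to Hz by dividing by
    ``n_events * binsize``, then optionally smoothed with a Gaussian kernel
    of SD ``kernel_sd`` seconds.
    """
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("events must be non-empty")
    if binsize <= 0:
        raise ValueError("binsize must be positive")
    n_bins = int(round((window[1] - window[0]) / binsize))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    edges = window[0] + np.arange(n_bins + 1) * binsize
    rel = event_relative_times(times, events, (edges[0], edges[-1]))
    counts, _ = np.histogram(rel, bins=edges)
    rate = counts / (events.size * binsize)
    if kernel_sd > 0:
        rate = gaussian_filter1d(rate, kernel_sd / binsize, mode="nearest")
    centers = (edges[:-1] + edges[1:]) / 2.0
    return Peth(
        bin_centers=centers,
        rate=rate,
        n_events=int(events.size),
        binsize=float(binsize),
        smoothing_sd=float(kernel_sd),
    )


def window_counts(
    times: np.ndarray, events: Sequence[float], window: Tuple[float, float]
) -> np.ndarray:
    """Per-event count of points in ``[event+window0, event+window1)``."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    lo = np.searchsorted(times, events + window[0], side="left")
    hi = np.searchsorted(times, events + window[1], side="left")
    return (hi - lo).astype(int)
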