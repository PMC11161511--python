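"""Single-unit spike-train analyses.

PETHs with baseline z-scoring, rank-test response classification,
session-half adaptation comparison, autocorrelograms with the burst index,
ISI-rule burst segmentation, K-means response clustering on principal
components, isolation-distance / L-ratio unit quality, and duplicate-unit
detection across recording depths.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import Peth, SpikeTrain, point_process_peth, window_counts

__all__ = [
    "Acg",
    "BurstSegmentation",
    "ResponseClass",
    "ClusterResult",
    "UnitQuality",
    "spike_peth",
    "zscore_peth",
    "classify_response",
    "session_half_comparison",
    "acg",
    "burst_index",
    "segment_bursts",
    "cluster_responses",
    "unit_quality",
    "duplicate_units",
]

DEFAULT_SPIKE_KERNEL_SD = 0.02  # s; resolves fast phasic responses


def spike_peth(
    spikes: SpikeTrain | np.ndarray,
    events: Sequence[float],
    window: Tuple[float, float] = (-2.0, 2.0),
    binsize: float = 0.01,
    kernel_sd: float = DEFAULT_SPIKE_KERNEL_SD,
) -> Peth:
    """Trial-averaged firing rate around events, Gaussian smoothed."""
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    return point_process_peth(times, events, window, binsize, kernel_sd)


def zscore_peth(peth: Peth, baseline_window: Tuple[float, float] = (-1.0, 0.0)) -> Peth:
    """Z-score a PETH by the mean and SD of its baseline bins.

    A zero-variance baseline is flagged ``degenerate`` (z set to 0) rather
    than silently divided; degenerate PETHs should be excluded from
    population averages.
    """
    mask = (peth.bin_centers >= baseline_window[0]) & (peth.bin_centers < baseline_window[1])
    if not np.any(mask):
        raise ValueError("baseline window contains no bins")
    mu = float(np.mean(peth.rate[mask]))
    sd = float(np.std(peth.rate[mask], ddof=1)) if mask.sum() > 1 else 0.0
    if sd <= 1e-12:
        return peth.copy_with(
            rate=np.zeros_like(peth.rate),
            zscored=True,
            degenerate=True,
            baseline_window=tuple(baseline_window),
        )
    return peth.copy_with(
        rate=(peth.rate - mu) / sd,
        zscored=True,
        degenerate=False,
        baseline_window=tuple(baseline_window),
    )


@dataclass
class ResponseClass:
    """Direction and significance of an event-locked rate change."""

    direction: str                  # "activated", "inhibited" or "none"
    p_activation: float
    p_inhibition: float
    baseline_rate: float            # Hz, mean across trials
    test_rate: float                # Hz, mean across trials
    n_trials: int
    alpha: float


def classify_response(
    spikes: SpikeTrain | np.ndarray,
    events: Sequence[float],
    baseline_events: Optional[Sequence[float]] = None,
    baseline: Tuple[float, float] = (-1.0, 0.0),
    test: Tuple[float, float] = (0.0, 0.5),
    alpha: float = 0.001,
) -> ResponseClass:
    """Classify a unit as activated/inhibited/none around events.

    Per-trial firing rates in the baseline window (relative to
    ``baseline_events``, by default the events themselves; pass cue onsets
    when testing reinforcement responses so the baseline is the pre-cue
    second of the same trial) are compared to rates in the test window by
    one-sided Mann-Whitney U tests in each direction.
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    events = np.asarray(events, dtype=float)
    base_ev = events if baseline_events is None else np.asarray(baseline_events, float)
    if events.size < 5 or base_ev.size != events.size:
        raise ValueError("need >= 5 trials with matching baseline events")
    b_len = baseline[1] - baseline[0]
    t_len = test[1] - test[0]
    base = window_counts(times, base_ev, baseline) / b_len
    tst = window_counts(times, events, test) / t_len
    if np.all(base == base[0]) and np.all(tst == tst[0]) and base[0] == tst[0]:
        p_act = p_inh = 1.0  # identical constant samples carry no evidence
    else:
        p_act = float(stats.mannwhitneyu(tst, base, alternative="greater").pvalue)
        p_inh = float(stats.mannwhitneyu(tst, base, alternative="less").pvalue)
    if p_act < alpha:
        direction = "activated"
    elif p_inh < alpha:
        direction = "inhibited"
    else:
        direction = "none"
    return ResponseClass(
        direction=direction,
        p_activation=p_act,
        p_inhibition=p_inh,
        baseline_rate=float(base.mean()),
        test_rate=float(tst.mean()),
        n_trials=int(events.size),
        alpha=alpha,
    )


def session_half_comparison(
    population: Sequence[Tuple[SpikeTrain | np.ndarray, Sequence[float]]],
    peak_window: Tuple[float, float] = (0.0, 0.5),
    baseline: Tuple[float, float] = (-1.0, 0.0),
    window: Tuple[float, float] = (-1.0, 1.0),
    binsize: float = 0.01,
    kernel_sd: float = DEFAULT_SPIKE_KERNEL_SD,
) -> Tuple[pd.DataFrame, dict]:
    """Compare event responses between session halves across units.

    Events of each unit are split at the median event index (first half gets
    the extra event when the count is odd). Per half, the peak of the
    smoothed PETH inside ``peak_window`` and the mean baseline rate are
    computed; across units each quantity is compared by a two-sided Wilcoxon
    signed-rank test. With a single unit only descriptive output is returned
    (p-values NaN).
    """
    rows = []
    for i, (spk, events) in enumerate(population):
        events = np.asarray(events, dtype=float)
        n_half = (events.size + 1) // 2
        if n_half < 4 or events.size - n_half < 4:
            raise ValueError("each unit needs >= 4 events per half")
        halves = (events[:n_half], events[n_half:])
        rec = {"unit": i}
        for name, ev in zip(("first", "second"), halves):
            p = spike_peth(spk, ev, window=window, binsize=binsize, kernel_sd=kernel_sd)
            times = spk.times if isinstance(spk, SpikeTrain) else np.asarray(spk, float)
            base = window_counts(times, ev, baseline) / (baseline[1] - baseline[0])
            rec[f"peak_{name}"] = p.peak(peak_window)
            rec[f"baseline_{name}"] = float(base.mean())
        rows.append(rec)
    table = pd.DataFrame(rows)
    out = {"n_units": len(table), "p_peak": np.nan, "p_baseline": np.nan}
    if len(table) > 1:
        for quantity in ("peak", "baseline"):
            diff = table[f"{quantity}_first"] - table[f"{quantity}_second"]
            if np.allclose(diff, 0):
                out[f"p_{quantity}"] = 1.0
            else:
                out[f"p_{quantity}"] = float(
                    stats.wilcoxon(
                        table[f"{quantity}_first"], table[f"{quantity}_second"]
                    ).pvalue
                )
    return table, out


@dataclass
class Acg:
    """Positive-half autocorrelogram at fixed lag resolution."""

    lags: np.ndarray                 # ms, bin centers, positive half
    counts: np.ndarray               # spike-pair coincidences per bin
    resolution: float                # ms
    n_spikes: int
    surrogate_mean: Optional[np.ndarray] = None
    surrogate_sd: Optional[np.ndarray] = None
    zscored: Optional[np.ndarray] = None   # (counts - mean)/sd where sd > 0


def acg(
    spikes: SpikeTrain | np.ndarray,
    resolution: float = 0.5,
    max_lag: float = 500.0,
    n_surrogates: int = 0,
    seed: int = 0,
) -> Acg:
    """Autocorrelogram of one unit at ``resolution`` ms.

    Counts all ordered spike pairs with lag in ``(0, max_lag]`` ms (zero-lag
    self pairs excluded). With ``n_surrogates > 0``, an ISI-shuffled
    surrogate ensemble provides a per-lag mean and SD used for z-scoring.
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    if times.size < 2:
        raise ValueError("autocorrelogram requires at least 2 spikes")
    edges_ms = np.arange(0.0, max_lag + resolution / 2, resolution)

    def _hist(ts: np.ndarray) -> np.ndarray:
        diffs = []
        k = 1
        max_s = max_lag / 1000.0
        while k < ts.size:
            d = ts[k:] - ts[:-k]
            d = d[d <= max_s]
            if d.size == 0:
                break
            diffs.append(d * 1000.0)
            k += 1
        pooled = np.concatenate(diffs) if diffs else np.empty(0)
        c, _ = np.histogram(pooled, bins=edges_ms)
        return c

    counts = _hist(times)
    result = Acg(
        lags=(edges_ms[:-1] + edges_ms[1:]) / 2.0,
        counts=counts,
        resolution=float(resolution),
        n_spikes=int(times.size),
    )
    if n_surrogates > 0:
        rng = np.random.default_rng(seed)
        isis = np.diff(times)
        sur = np.empty((n_surrogates, counts.size))
        for s in range(n_surrogates):
            shuffled = times[0] + np.concatenate(
                [[0.0], np.cumsum(rng.permutation(isis))]
            )
            sur[s] = _hist(shuffled)
        mean = sur.mean(axis=0)
        sd = sur.std(axis=0, ddof=1)
        z = np.zeros_like(mean)
        ok = sd > 0
        z[ok] = (counts[ok] - mean[ok]) / sd[ok]
        result.surrogate_mean = mean
        result.surrogate_sd = sd
        result.zscored = z
    return result


def burst_index(correlogram: Acg) -> float:
    """Burst index from an autocorrelogram, bounded in [-1, 1].

    BI = (max ACG over 0-10 ms lags - mean ACG over 180-200 ms lags),
    normalized by the greater of the two; 0 when both are 0. Values above
    0.3 are the conventional bursting criterion.
    """
    lags = correlogram.lags
    if lags[-1] + correlogram.resolution / 2 < 200.0:
        raise ValueError("autocorrelogram must cover lags up to 200 ms")
    short = correlogram.counts[(lags > 0.0) & (lags <= 10.0)]
    long = correlogram.counts[(lags >= 180.0) & (lags <= 200.0)]
    peak = float(short.max()) if short.size else 0.0
    tail = float(long.mean()) if long.size else 0.0
    denom = max(peak, tail)
    if denom == 0.0:
        return 0.0
    return (peak - tail) / denom


@dataclass
class BurstSegmentation:
    """ISI-rule burst partition of one spike train."""

    burst_id: np.ndarray             # per spike; -1 marks single spikes
    bursts: pd.DataFrame             # columns: burst, start, end, n_spikes

    @property
    def n_bursts(self) -> int:
        return int(len(self.bursts))

    @property
    def burst_fraction(self) -> float:
        """Fraction of spikes that are part of a burst."""
        if self.burst_id.size == 0:
            return 0.0
        return float(np.mean(self.burst_id >= 0))


def segment_bursts(
    spikes: SpikeTrain | np.ndarray,
    start_isi: float = 0.010,
    continue_isi: float = 0.015,
) -> BurstSegmentation:
    """Partition a spike train into bursts and single spikes.

    A burst starts whenever an ISI drops below ``start_isi`` (10 ms) and
    extends as long as subsequent ISIs stay below ``continue_isi`` (15 ms).
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    ids = np.full(times.size, -1, dtype=int)
    rows = []
    i = 0
    burst = 0
    while i < times.size - 1:
        if times[i + 1] - times[i] < start_isi:
            j = i + 1
            while j < times.size - 1 and times[j + 1] - times[j] < continue_isi:
                j += 1
            ids[i : j + 1] = burst
            rows.append((burst, times[i], times[j], j - i + 1))
            burst += 1
            i = j + 1
        else:
            i += 1
    bursts = pd.DataFrame(rows, columns=["burst", "start", "end", "n_spikes"])
    return BurstSegmentation(burst_id=ids, bursts=bursts)


@dataclass
class ClusterResult:
    """Population clustering of z-scored response profiles."""

    labels: np.ndarray               # 1-based; cluster 1 has the highest tagged fraction
    tagged_fraction: np.ndarray      # per cluster, index 0 <-> cluster 1
    sizes: np.ndarray
    pcs: np.ndarray                  # unit x n_pc principal-component scores
    n_effective: int                 # clusters holding at least one unit
    degenerate: bool                 # fewer distinct centers than requested


def cluster_responses(
    zpeths: np.ndarray,
    tagged_flags: Sequence[bool],
    k: int = 5,
    n_pc: int = 3,
    seed: int = 0,
    n_init: int = 50,
) -> ClusterResult:
    """K-means clustering of z-scored PETHs on leading principal components.

    ``zpeths`` is a unit x bin matrix (PETHs for both cues concatenated per
    unit). Principal components are computed on that matrix, K-means is run
    on the first ``n_pc`` scores, and clusters are renumbered 1..k in
    descending order of the fraction of optogenetically tagged units they
    contain (ties broken by cluster size).
    """
    zpeths = np.asarray(zpeths, dtype=float)
    tagged = np.asarray(tagged_flags, dtype=bool)
    if zpeths.ndim != 2 or zpeths.shape[0] != tagged.size:
        raise ValueError("zpeths must be a unit x bin matrix matching tagged_flags")
    if k > zpeths.shape[0]:
        raise ValueError("cannot form more clusters than units")
    n_pc = min(n_pc, zpeths.shape[1], zpeths.shape[0])
    pcs = PCA(n_components=n_pc, random_state=seed).fit_transform(zpeths)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(pcs)
    raw = km.labels_
    frac = np.array([tagged[raw == c].mean() if np.any(raw == c) else 0.0 for c in range(k)])
    size = np.array([(raw == c).sum() for c in range(k)])
    order = np.lexsort((-size, -frac))  # descending tagged fraction, then size
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw]
    distinct = np.unique(np.round(km.cluster_centers_, 10), axis=0).shape[0]
    return ClusterResult(
        labels=labels,
        tagged_fraction=frac[order],
        sizes=size[order],
        pcs=pcs,
        n_effective=int(np.unique(raw).size),
        degenerate=distinct < k,
    )


@dataclass
class UnitQuality:
    """Cluster-isolation metrics of one sorted unit."""

    isolation_distance: float
    l_ratio: float
    n_cluster: int
    n_noise: int
    passes: bool                     # isolation distance > 20 and L-ratio < 0.15


def unit_quality(
    cluster_features: np.ndarray,
    noise_features: np.ndarray,
    id_threshold: float = 20.0,
    lratio_threshold: float = 0.15,
) -> UnitQuality:
    """Isolation distance and L-ratio of a spike cluster.

    Squared Mahalanobis distances of noise spikes are computed under the
    cluster's own covariance. Isolation distance is the distance of the
    n_cluster-th closest noise spike (NaN when fewer noise spikes exist);
    L-ratio is ``sum(1 - chi2_d.cdf(D2)) / n_cluster``.
    """
    cl = np.atleast_2d(np.asarray(cluster_features, dtype=float))
    ns = np.atleast_2d(np.asarray(noise_features, dtype=float))
    if cl.shape[1] != ns.shape[1] or cl.shape[1] < 1:
        raise ValueError("feature dimensions must match and be >= 1")
    d = cl.shape[1]
    cov = np.cov(cl, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular cluster covariance; reduce the feature dimension or add spikes"
        ) from exc
    mu = cl.mean(axis=0)
    delta = ns - mu
    d2 = np.einsum("ij,jk,ik->i", delta, cov_inv, delta)
    n_cluster = cl.shape[0]
    if ns.shape[0] >= n_cluster:
        iso = float(np.sort(d2)[n_cluster - 1])
    else:
        iso = float("nan")
    l_ratio = float(np.sum(1.0 - stats.chi2.cdf(d2, df=d)) / n_cluster)
    passes = bool(iso > id_threshold and l_ratio < lratio_threshold)
    return UnitQuality(
        isolation_distance=iso,
        l_ratio=l_ratio,
        n_cluster=n_cluster,
        n_noise=ns.shape[0],
        passes=passes,
    )


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def duplicate_units(
    units: Sequence[SpikeTrain],
    waveform_r_min: float = 0.95,
    acg_cos_min: float = 0.9,
    max_depth_um: float = 200.0,
    acg_max_lag: float = 100.0,
) -> List[List[int]]:
    """Group probable duplicate recordings of the same neuron.

    Units on the same tetrode within ``max_depth_um`` dorso-ventral distance
    are compared by mean-waveform Pearson correlation and autocorrelogram
    cosine similarity; pairs exceeding both thresholds are linked and
    connected components returned (each group should be counted once in
    population sizes). Pairs with a missing waveform are skipped with a
    warning.
    """
    n = len(units)
    rows, cols = [], []
    acgs: dict[int, np.ndarray] = {}

    def _acg_counts(i: int) -> np.ndarray:
        if i not in acgs:
            acgs[i] = acg(units[i], resolution=0.5, max_lag=acg_max_lag).counts.astype(float)
        return acgs[i]

    for i in range(n):
        for j in range(i + 1, n):
            a, b = units[i], units[j]
            if a.tetrode is None or b.tetrode is None or a.tetrode != b.tetrode:
                continue
            if a.depth_um is None or b.depth_um is None:
                continue
            if abs(a.depth_um - b.depth_um) > max_depth_um:
                continue
            if a.waveform is None or b.waveform is None:
                warnings.warn(
                    f"skipping duplicate check for units {a.unit_id}/{b.unit_id}: missing waveform"
                )
                continue
            wa, wb = a.waveform.ravel(), b.waveform.ravel()
            if wa.size != wb.size:
                warnings.warn(
                    f"skipping duplicate check for units {a.unit_id}/{b.unit_id}: waveform shapes differ"
                )
                continue
            r = float(np.corrcoef(wa, wb)[0, 1])
            cos = _cosine(_acg_counts(i), _acg_counts(j))
            if r >= waveform_r_min and cos >= acg_cos_min:
                rows.append(i)
                cols.append(j)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, comp = connected_components(adj, directed=False)
    groups = [list(np.flatnonzero(comp == c)) for c in range(n_comp)]
    return [g for g in groups if len(g) > 1]
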