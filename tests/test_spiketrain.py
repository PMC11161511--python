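"""Spike-train analyses: PETH/z-score identities, rank tests, ACG/bursts,
clustering, quality metrics and duplicate detection."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from bfphys.core import Peth, SpikeTrain
from bfphys.spiketrain import (
    Acg,
    acg,
    burst_index,
    classify_response,
    cluster_responses,
    duplicate_units,
    segment_bursts,
    session_half_comparison,
    spike_peth,
    unit_quality,
    zscore_peth,
)
from bfphys.synthetic import ResponseProfile, event_times, generate_spike_train


def _make_peth(rates, binsize=0.1, start=-1.0):
    rates = np.asarray(rates, float)
    centers = start + (np.arange(rates.size) + 0.5) * binsize
    return Peth(bin_centers=centers, rate=rates, n_events=10, binsize=binsize)


class TestPethAndZscore:
    def test_spike_at_event_fills_single_bin(self):
        events = np.arange(5.0, 55.0, 5.0)
        spikes = np.sort(events + 0.0005)
        p = spike_peth(spikes, events, window=(-0.01, 0.01), binsize=0.001, kernel_sd=0.0)
        assert p.rate.max() == pytest.approx(1000.0)
        assert p.rate.sum() == pytest.approx(1000.0)

    def test_responder_peak_near_configured_latency(self, punishment_session, punishment_responder_profile):
        trials, _ = punishment_session
        profile = ResponseProfile(
            baseline_rate=5.0, gains={"punishment": 8.0},
            latency=0.05, jitter=0.005, response_duration=0.05,
        )
        spk = generate_spike_train(trials, profile, seed=4)
        ev = event_times(trials, "punishment")
        p = spike_peth(spk, ev, window=(-0.5, 0.5), binsize=0.005)
        peak_t = p.bin_centers[np.argmax(p.rate)]
        assert abs(peak_t - 0.05) < 0.1

    def test_zscore_arithmetic(self):
        p = _make_peth([1.0, 2.0, 3.0] + [4.0] * 7, binsize=1 / 3, start=-1.0)
        z = zscore_peth(p, baseline_window=(-1.0, 0.0))
        # baseline bins {1,2,3}: mean 2, SD 1 -> test bins at 4 give z = 2
        assert np.allclose(z.rate[3:], 2.0)
        assert abs(z.rate[:3].mean()) < 1e-9
        assert abs(np.std(z.rate[:3], ddof=1) - 1.0) < 1e-9

    def test_constant_peth_flagged_degenerate(self):
        z = zscore_peth(_make_peth(np.full(20, 7.0)))
        assert z.degenerate
        assert np.allclose(z.rate, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 50, allow_nan=False), min_size=12, max_size=40),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_zscore_invariant_to_affine_rescaling(self, rates, a, b):
        p = _make_peth(rates, binsize=2.0 / len(rates), start=-1.0)
        z1 = zscore_peth(p)
        z2 = zscore_peth(p.copy_with(rate=a * p.rate + b))
        if not z1.degenerate:
            assert np.allclose(z1.rate, z2.rate, atol=1e-6)


class TestClassifyResponse:
    def test_fully_separated_counts_activate(self):
        events = np.arange(10.0, 310.0, 10.0)
        # 5 baseline spikes in (-1, 0), 20 test spikes in (0, 0.5) per trial
        spikes = np.sort(
            np.concatenate(
                [events[:, None] + np.linspace(-0.9, -0.1, 5)[None, :],
                 events[:, None] + np.linspace(0.01, 0.49, 20)[None, :]],
                axis=None,
            )
        )
        r = classify_response(spikes, events)
        assert r.direction == "activated"
        assert r.p_activation < 1e-6
        assert r.baseline_rate == pytest.approx(5.0)
        assert r.test_rate == pytest.approx(40.0)

    def test_silenced_test_window_inhibits(self):
        events = np.arange(10.0, 210.0, 10.0)
        spikes = np.sort((events[:, None] + np.linspace(-0.9, -0.1, 5)[None, :]).ravel())
        r = classify_response(spikes, events)
        assert r.direction == "inhibited"

    def test_too_few_trials_raise(self):
        with pytest.raises(ValueError):
            classify_response(np.array([1.0, 2.0]), [1.0, 2.0, 3.0])


class TestSessionHalves:
    def test_adaptation_detected_across_units(self, punishment_session):
        trials, _ = punishment_session
        ev = event_times(trials, "punishment")
        pop = []
        for u in range(30):
            profile = ResponseProfile(baseline_rate=5.0, gains={"punishment": 6.0}, adaptation=0.96)
            pop.append((generate_spike_train(trials, profile, seed=500 + u), ev))
        table, stats_out = session_half_comparison(pop)
        assert (table["peak_first"] > table["peak_second"]).mean() > 0.5
        assert stats_out["p_peak"] < 0.05
        assert np.median(table["peak_first"] - table["peak_second"]) > 0

    def test_single_unit_descriptive_only(self, punishment_session):
        trials, _ = punishment_session
        ev = event_times(trials, "punishment")
        profile = ResponseProfile(baseline_rate=5.0, gains={"punishment": 4.0})
        spk = generate_spike_train(trials, profile, seed=9)
        table, stats_out = session_half_comparison([(spk, ev)])
        assert len(table) == 1
        assert np.isnan(stats_out["p_peak"])


def _acg_bruteforce(times_s, resolution=0.5, max_lag=500.0):
    t = np.asarray(times_s) * 1000.0
    diffs = [b - a for i, a in enumerate(t) for b in t[i + 1:] if 0 < b - a <= max_lag]
    edges = np.arange(0.0, max_lag + resolution / 2, resolution)
    counts, _ = np.histogram(diffs, bins=edges)
    return counts


class TestAcgAndBursts:
    def test_exhaustive_pair_enumeration(self):
        # equally spaced spikes: 3 pairs at one step, 2 at two, 1 at three
        # (10.2 ms spacing keeps every lag interior to a 0.5 ms bin)
        spikes = np.array([0.0, 0.0102, 0.0204, 0.0306])
        a = acg(spikes, resolution=0.5, max_lag=50.0)
        nz = a.counts > 0
        assert np.array_equal(a.counts[nz], [3, 2, 1])
        assert np.allclose(a.lags[nz], [10.25, 20.25, 30.75])
        assert a.counts.sum() == 6

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_on_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        times = np.sort(rng.uniform(0, 5.0, n))
        times = times[np.concatenate([[True], np.diff(times) > 1e-4])]
        if times.size < 2:
            return
        a = acg(times, resolution=0.5, max_lag=500.0)
        assert np.array_equal(a.counts, _acg_bruteforce(times))

    def test_single_spike_errors(self):
        with pytest.raises(ValueError):
            acg(np.array([1.0]))

    def test_poisson_acg_flat_under_surrogate_normalization(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 120.0, 2400))  # 20 Hz homogeneous
        a = acg(times, resolution=0.5, max_lag=200.0, n_surrogates=100, seed=1)
        assert np.all(np.abs(a.zscored) < 4.0)

    def test_burst_index_formula_and_bounds(self):
        lags = np.arange(0.25, 500.0, 0.5)
        counts = np.zeros(lags.size)
        counts[(lags > 0) & (lags <= 10)] = [8 if i == 3 else 1 for i in range(20)]
        counts[(lags >= 180) & (lags <= 200)] = 2
        a = Acg(lags=lags, counts=counts, resolution=0.5, n_spikes=100)
        assert burst_index(a) == pytest.approx(0.75)
        counts2 = np.full(lags.size, 5.0)
        assert burst_index(Acg(lags=lags, counts=counts2, resolution=0.5, n_spikes=10)) == 0.0
        zero = Acg(lags=lags, counts=np.zeros(lags.size), resolution=0.5, n_spikes=2)
        assert burst_index(zero) == 0.0

    def test_bursty_vs_poisson_burst_index(self, punishment_session):
        # full-session recordings: ~40 min gives the ACG enough pairs for the
        # max-vs-mean index to settle near 0 for a homogeneous train
        trials, _ = punishment_session
        bursty = generate_spike_train(
            trials, ResponseProfile(baseline_rate=8.0, burstiness=0.6), seed=21,
            duration=2400.0,
        )
        poisson = generate_spike_train(
            trials, ResponseProfile(baseline_rate=10.0, burstiness=0.0), seed=22,
            duration=2400.0,
        )
        assert burst_index(acg(bursty, max_lag=200.0)) > 0.3
        assert abs(burst_index(acg(poisson, max_lag=200.0))) < 0.3

    def test_burst_segmentation_hand_examples(self):
        times = np.array([0.0, 0.005, 0.012, 0.040, 0.048, 0.060, 0.100])
        seg = segment_bursts(times)
        assert seg.n_bursts == 2
        assert np.array_equal(seg.burst_id, [0, 0, 0, 1, 1, 1, -1])
        assert seg.bursts.loc[0, "n_spikes"] == 3
        assert segment_bursts(np.array([0.0, 0.012])).n_bursts == 0
        empty = segment_bursts(np.empty(0))
        assert empty.n_bursts == 0 and empty.burst_id.size == 0

    def test_burst_invariants_on_random_trains(self, rng):
        for _ in range(50):
            times = np.sort(rng.uniform(0, 2.0, rng.integers(2, 300)))
            times = times[np.concatenate([[True], np.diff(times) > 1e-4])]
            seg = segment_bursts(times)
            for _, row in seg.bursts.iterrows():
                member = times[(times >= row.start) & (times <= row.end)]
                isis = np.diff(member)
                assert row.n_spikes >= 2
                assert isis[0] < 0.010
                assert np.all(isis < 0.015)


def _archetype_bank(rng, n_per=20, n_bins=80, noise_sd=0.1):
    t = np.linspace(0, 1, n_bins)
    templates = [
        np.exp(-((t - c) ** 2) / (2 * 0.05 ** 2)) * s
        for c, s in [(0.1, 3.0), (0.3, -2.0), (0.5, 2.5), (0.7, 3.5), (0.9, -3.0)]
    ]
    X, labels = [], []
    for k, tpl in enumerate(templates):
        X.append(tpl[None, :] + noise_sd * rng.standard_normal((n_per, n_bins)))
        labels += [k] * n_per
    return np.vstack(X), np.asarray(labels)


class TestClustering:
    def test_recovers_archetypes(self, rng):
        X, truth = _archetype_bank(rng)
        tagged = truth == 2
        res = cluster_responses(X, tagged, k=5, n_pc=3, seed=0)
        assert adjusted_rand_score(truth, res.labels) >= 0.9
        # the archetype holding the tagged units becomes cluster 1
        assert np.all(res.labels[tagged] == 1)
        assert res.tagged_fraction[0] == pytest.approx(1.0)

    def test_identical_units_flagged_degenerate(self):
        X = np.tile(np.linspace(0, 1, 40), (10, 1))
        res = cluster_responses(X, np.zeros(10, bool), k=3, n_pc=2, seed=0)
        assert res.degenerate or res.n_effective < 3

    def test_more_clusters_than_units_rejected(self):
        with pytest.raises(ValueError):
            cluster_responses(np.zeros((3, 10)), [False] * 3, k=5)


class TestUnitQuality:
    def test_well_separated_cluster(self, rng):
        cl = rng.standard_normal((100, 2))
        ns = rng.standard_normal((200, 2)) + np.array([10.0, 0.0])
        q = unit_quality(cl, ns)
        assert q.isolation_distance > 50.0
        assert q.l_ratio < 1e-6
        assert q.passes

    def test_noise_from_cluster_distribution_fails(self, rng):
        cl = rng.standard_normal((100, 2))
        ns = rng.standard_normal((100, 2))
        q = unit_quality(cl, ns)
        assert q.l_ratio > 0.2
        assert q.isolation_distance < 20.0
        assert not q.passes

    def test_threshold_gate(self, rng):
        cl = rng.standard_normal((50, 2))
        near = rng.standard_normal((50, 2)) + np.array([3.0, 0.0])
        q = unit_quality(cl, near)
        # pass/fail tracks the ID > 20 and L-ratio < 0.15 gates exactly
        assert q.passes == (q.isolation_distance > 20.0 and q.l_ratio < 0.15)

    def test_singular_covariance_guidance(self):
        cl = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError, match="dimension"):
            unit_quality(cl, cl + 1.0)


class TestDuplicates:
    def _unit(self, times, uid, wf, depth, tet=1):
        return SpikeTrain(times=times, unit_id=uid, waveform=wf, depth_um=depth, tetrode=tet)

    def test_identical_unit_grouped(self, rng):
        times = np.sort(rng.uniform(0, 60.0, 600))
        times = times[np.concatenate([[True], np.diff(times) > 1e-3])]
        wf = np.sin(np.linspace(0, 3 * np.pi, 32))
        a = self._unit(times, "a", wf, 1000.0)
        b = self._unit(times + 0.0004, "b", wf + 0.01, 1050.0)
        groups = duplicate_units([a, b])
        assert groups == [[0, 1]]

    def test_depth_rule_excludes_distant_pairs(self, rng):
        times = np.sort(rng.uniform(0, 60.0, 600))
        times = times[np.concatenate([[True], np.diff(times) > 1e-3])]
        wf = np.sin(np.linspace(0, 3 * np.pi, 32))
        a = self._unit(times, "a", wf, 1000.0)
        b = self._unit(times + 0.0004, "b", wf, 1300.0)  # 300 um apart
        assert duplicate_units([a, b]) == []

    def test_independent_units_not_grouped(self, rng):
        t1 = np.sort(rng.uniform(0, 60.0, 500))
        t2 = np.sort(rng.uniform(0, 60.0, 500))
        wf1 = np.sin(np.linspace(0, 3 * np.pi, 32))
        wf2 = np.cos(np.linspace(0, 5 * np.pi, 32))
        a = self._unit(t1, "a", wf1, 1000.0)
        b = self._unit(t2, "b", wf2, 1020.0)
        assert duplicate_units([a, b]) == []
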