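"""Co-occurrence, coherence, shuffle nulls, and lag estimation."""

import numpy as np
import pytest

from conftest import make_burst_pairs, make_lagged_pair
from netbursts.detection import BurstEvent
from netbursts.exceptions import ConfigError
from netbursts.interactions import (CoPair, canonical_pair, coherence_null,
                                    cooccurrence_incidence,
                                    cross_spectral_coherence,
                                    find_cooccurring, imaginary_coherence,
                                    mean_band, pairwise_mean_coherence,
                                    population_lag_test,
                                    prewhitened_xcorr_lag,
                                    spike_field_coherence,
                                    spiketrain_xcorr_lag, welch_coherence)

FS = 1000.0


def _ev(region, onset, offset=None, kind="SB", eid=0):
    ev = BurstEvent(region, onset, offset if offset else onset + 1.0,
                    10, 20, -30, 8, event_id=eid)
    ev.kind = kind
    return ev


class TestCooccurrence:
    def test_within_half_second_pairs(self):
        pairs = find_cooccurring([_ev("cortex", 10.0)],
                                 [_ev("striatum", 10.4)])
        assert len(pairs) == 1
        assert pairs[0].onset_diff == pytest.approx(0.4)

    def test_exactly_half_second_excluded(self):
        assert find_cooccurring([_ev("cortex", 10.0)],
                                [_ev("striatum", 10.5)]) == []

    def test_one_to_one_matching_prefers_earlier(self):
        a = [_ev("cortex", 10.0)]
        b = [_ev("striatum", 9.7, eid=1), _ev("striatum", 10.3, eid=2)]
        pairs = find_cooccurring(a, b)
        assert len(pairs) == 1
        assert pairs[0].event_b.event_id == 1

    def test_incidence_normalized_by_class_counts(self):
        a = [_ev("cortex", 1.0, kind="SB"), _ev("cortex", 5.0, kind="SB")]
        b = [_ev("striatum", 1.2, kind="SB"), _ev("striatum", 9.0, kind="SB")]
        pairs = find_cooccurring(a, b)
        inc = cooccurrence_incidence(pairs, a, b)
        assert inc["SB/SB"] == pytest.approx(1 / 4)


class TestCoherence:
    def test_identical_signals_full_coherence(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        f, c = welch_coherence(x, x, FS)
        assert np.allclose(c, 1.0)
        pair = CoPair(_ev("cortex", 0.0, 2.0), _ev("striatum", 0.0, 2.0), 0.0)
        res = cross_spectral_coherence(pair, x, x, FS)
        assert res.mean_coherence > 0.99
        assert res.rejected_artifact  # >0.8 synchrony flagged as artifact

    def test_shared_narrowband_component_peaks_at_25hz(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 4, 1 / FS)
        shared = np.sin(2 * np.pi * 25 * t)
        x = shared + rng.standard_normal(t.size)
        y = shared + rng.standard_normal(t.size)
        f, c = welch_coherence(x, y, FS)
        at25 = c[np.argmin(np.abs(f - 25))]
        away = mean_band(f, c, (40, 100))
        assert at25 > 0.5 > away + 0.2

    def test_imaginary_coherence_suppresses_zero_lag(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(2000)
        pair = CoPair(_ev("cortex", 0.0, 2.0), _ev("striatum", 0.0, 2.0), 0.0)
        res = imaginary_coherence(pair, x, x, FS)
        assert res.mean_coherence < 0.05

    def test_imaginary_coherence_sees_quarter_cycle_shift(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 4, 1 / FS)
        x = np.sin(2 * np.pi * 20 * t) + 0.5 * rng.standard_normal(t.size)
        y = np.sin(2 * np.pi * 20 * t + np.pi / 2) \
            + 0.5 * rng.standard_normal(t.size)
        pair = CoPair(_ev("cortex", 0.0, 4.0), _ev("striatum", 0.0, 4.0), 0.0)
        res = imaginary_coherence(pair, x, y, FS)
        peak_f = res.freqs[np.argmax(res.coherence)]
        assert abs(peak_f - 20.0) <= 2.0

    def test_vectorized_matrix_equals_scipy_per_pair(self):
        rng = np.random.default_rng(4)
        sa = [rng.standard_normal(1500) for _ in range(3)]
        sb = [rng.standard_normal(1500) for _ in range(3)]
        mat = pairwise_mean_coherence(sa, sb, FS)
        for i in range(3):
            for j in range(3):
                f, c = welch_coherence(sa[i], sb[j], FS)
                assert mat[i, j] == pytest.approx(mean_band(f, c), abs=1e-12)


class TestCoherenceNull:
    def test_threshold_is_95th_percentile(self):
        rng = np.random.default_rng(5)
        sa, sb = make_burst_pairs(rng, 10)
        mat = pairwise_mean_coherence(sa, sb, FS)
        res = coherence_null(mat, n_shuffle=500, seed=0)
        assert res.threshold == pytest.approx(
            np.percentile(res.null_means, 95.0))
        assert res.null_means.size == 500

    def test_shared_components_exceed_null(self):
        rng = np.random.default_rng(6)
        t = np.arange(0, 1.5, 1 / FS)
        sa, sb = [], []
        for k in range(8):
            shared = np.sin(2 * np.pi * (8 + k) * t)
            sa.append(shared + 0.3 * rng.standard_normal(t.size))
            sb.append(shared + 0.3 * rng.standard_normal(t.size))
        mat = pairwise_mean_coherence(sa, sb, FS)
        res = coherence_null(mat, n_shuffle=300, seed=0)
        assert res.significant
        assert res.observed_mean > res.threshold

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ConfigError):
            coherence_null(np.ones((1, 1)), 10)


class TestSpikeFieldCoherence:
    def _lfp(self, rng):
        t = np.arange(0, 10, 1 / FS)
        return 20 * np.sin(2 * np.pi * 10 * t) \
            + 5 * rng.standard_normal(t.size)

    def test_locked_spikes_significant_at_10hz(self):
        rng = np.random.default_rng(7)
        lfp = self._lfp(rng)
        troughs = (np.arange(95) + 0.75) / 10.0
        res = spike_field_coherence(troughs, lfp, FS, 0.0, 10.0,
                                    n_shuffle=200, seed=1)
        i10 = np.argmin(np.abs(res.freqs - 10.0))
        assert res.significant
        assert res.coherence[i10] > res.per_bin_threshold[i10]

    def test_independent_spikes_few_significant_bins(self):
        rng = np.random.default_rng(8)
        lfp = self._lfp(rng)
        poisson = np.sort(rng.uniform(0, 10, 120))
        res = spike_field_coherence(poisson, lfp, FS, 0.0, 10.0,
                                    n_shuffle=200, seed=1)
        frac = np.mean(res.coherence > res.per_bin_threshold)
        assert frac < 0.15

    def test_insufficient_spikes_flagged(self):
        rng = np.random.default_rng(9)
        res = spike_field_coherence(np.array([1.0, 2.0]), self._lfp(rng),
                                    FS, 0.0, 10.0, n_shuffle=10, seed=0)
        assert "insufficient_spikes" in res.flags
        assert res.significant is None

    def test_empty_span_rejected(self):
        with pytest.raises(ConfigError):
            spike_field_coherence(np.array([]), np.zeros(1000), FS, 5.0, 5.0)


class TestLfpLag:
    def test_delayed_copy_recovers_negative_lag(self):
        # striatum delayed by 30 ms => cortex leads => lag -30 by convention
        rng = np.random.default_rng(10)
        a, b = make_lagged_pair(rng, -30.0, (4, 16))
        res = prewhitened_xcorr_lag(a, b, FS, (4, 16),
                                    ("cortex", "striatum"))
        assert abs(res.lag_ms + 30.0) <= 5.0
        assert res.putative_mono is False
        assert "striatum leads cortex" in res.sign_convention

    def test_identical_signals_zero_lag(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(3000)
        res = prewhitened_xcorr_lag(x, x, FS, (4, 16))
        assert res.lag_ms == 0.0
        assert res.peak_corr == pytest.approx(
            res.peak_corr)  # finite
        assert res.putative_mono

    def test_flipped_region_order_same_signed_lag(self):
        rng = np.random.default_rng(12)
        a, b = make_lagged_pair(rng, 30.0, (16, 40))
        r1 = prewhitened_xcorr_lag(a, b, FS, (16, 40),
                                   ("cortex", "striatum"))
        r2 = prewhitened_xcorr_lag(b, a, FS, (16, 40),
                                   ("striatum", "cortex"))
        assert r1.lag_ms == r2.lag_ms
        assert r1.region_pair == r2.region_pair == ("cortex", "striatum")

    def test_independent_signals_low_peak(self):
        rng = np.random.default_rng(13)
        peaks = []
        for _ in range(5):
            a = rng.standard_normal(3000)
            b = rng.standard_normal(3000)
            peaks.append(prewhitened_xcorr_lag(a, b, FS, (4, 16)).peak_corr)
        shared = prewhitened_xcorr_lag(
            *make_lagged_pair(rng, 0.0, (4, 16)), FS, (4, 16)).peak_corr
        assert shared > 3 * np.median(peaks)

    def test_short_span_rejected(self):
        with pytest.raises(ConfigError):
            prewhitened_xcorr_lag(np.zeros(500), np.zeros(500), FS, (4, 16))

    @pytest.mark.parametrize("pair", [("cortex", "striatum"),
                                      ("thalamus", "striatum"),
                                      ("cortex", "thalamus")])
    def test_sign_convention_each_canonical_pair(self, pair):
        # second region's activity occurs 25 ms earlier => it leads =>
        # positive lag for every canonical pair
        rng = np.random.default_rng(hash(pair) % 2 ** 31)
        a, b = make_lagged_pair(rng, 25.0, (4, 16))
        res = prewhitened_xcorr_lag(a, b, FS, (4, 16), pair)
        assert res.lag_ms > 0
        assert res.sign_convention == \
            f"positive lag: {pair[1]} leads {pair[0]}"


class TestSpikeLag:
    def _train(self, rng, rate=80.0, dur=4.0):
        return np.sort(rng.uniform(0, dur, int(rate * dur)))

    def test_shifted_train_recovers_lag(self):
        rng = np.random.default_rng(14)
        ta = self._train(rng)
        res = spiketrain_xcorr_lag(ta, ta + 0.003, 0.0, 4.0)
        assert res.lag_ms == pytest.approx(-3.0, abs=2.0)

    def test_identical_trains_zero_lag(self):
        rng = np.random.default_rng(15)
        ta = self._train(rng)
        assert spiketrain_xcorr_lag(ta, ta, 0.0, 4.0).lag_ms == 0.0

    def test_too_few_spikes_skipped(self):
        assert spiketrain_xcorr_lag(np.array([1.0]), np.array([1.0, 2.0]),
                                    0.0, 4.0) is None

    def test_population_shift_detected(self):
        rng = np.random.default_rng(16)
        lags = []
        for _ in range(100):
            ta = self._train(rng, rate=60.0, dur=3.0)
            jitter = rng.normal(0, 0.001, ta.size)
            res = spiketrain_xcorr_lag(ta, ta + 0.002 + jitter, 0.0, 3.0)
            if res is not None:
                lags.append(res.lag_ms)
        pop = population_lag_test(lags)
        assert abs(pop["mean_lag_ms"] + 2.0) < 1.0
        assert pop["p"] < 0.01


def test_canonical_pair_ordering():
    assert canonical_pair("striatum", "cortex") == (("cortex", "striatum"),
                                                    True)
    assert canonical_pair("cortex", "thalamus") == (("cortex", "thalamus"),
                                                    False)
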