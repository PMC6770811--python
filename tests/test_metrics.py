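"""Spike-train metrics: rates, PSTH, net evoked activity, bursts, CV2."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spikephys import (AnalysisConfig, BurstCriteria, Epoch, NeuronRecord,
                       SpikeTrain, ValidationError, burst_rate, compute_isis,
                       cv2_series, detect_bursts, firing_rate, joint_isi_map,
                       net_evoked_rate, psth, summarize_neuron)
from spikephys.metrics import BurstEvent

from conftest import bursty_random_train, oracle_bursts, poisson_train


def train(ts, t_start=0.0, t_stop=None):
    ts = np.asarray(ts, dtype=float)
    return SpikeTrain(ts, t_start, t_stop if t_stop is not None
                      else float(ts[-1]) + 1e-9 if ts.size else 1.0)


class TestIsis:
    def test_simple(self):
        np.testing.assert_allclose(compute_isis(train([0.0, 0.1, 0.25])),
                                   [0.1, 0.15])

    def test_regular_train(self):
        tr = train(np.arange(10) * 0.2 + 0.1)
        np.testing.assert_allclose(compute_isis(tr), 0.2)

    def test_telescoping_sum(self, rng):
        tr = bursty_random_train(rng)
        assert compute_isis(tr).sum() == pytest.approx(
            tr.timestamps[-1] - tr.timestamps[0])

    def test_fewer_than_two_spikes_gives_empty(self):
        assert compute_isis(train([0.5])).size == 0


class TestFiringRate:
    def test_spikes_per_second(self):
        tr = train(np.linspace(0.1, 14.9, 30), 0.0, 15.0)
        assert firing_rate(tr, Epoch("background", 0, 15)) == 2.0

    def test_empty_epoch_is_zero(self):
        tr = train([20.0], 0.0, 30.0)
        assert firing_rate(tr, Epoch("background", 0, 15)) == 0.0

    def test_half_open_boundary(self):
        # spike exactly at epoch end is excluded; at onset included
        tr = train([0.0, 7.0, 15.0], 0.0, 20.0)
        assert firing_rate(tr, Epoch("background", 0, 15)) * 15 == 2


class TestNetEvoked:
    def _tr(self, stim_rate, bg_rate):
        bg = np.arange(0.0, 300.0, 1.0 / bg_rate)
        stim = np.arange(300.0, 315.0, 1.0 / stim_rate) + 1e-4
        ts = np.unique(np.concatenate([bg, stim]))
        return SpikeTrain(ts, 0.0, 320.0)

    def test_subtraction(self):
        tr = self._tr(4.0, 2.0)
        net = net_evoked_rate(tr, Epoch("noxious", 300, 15), 120.0)
        assert net == pytest.approx(2.0, abs=0.05)

    def test_identical_rates_give_zero(self):
        tr = SpikeTrain(np.arange(0.5, 400, 0.5), 0.0, 400.0)
        assert net_evoked_rate(tr, Epoch("noxious", 300, 15), 120.0) == \
            pytest.approx(0.0, abs=1e-9)

    def test_insufficient_prestimulus_time_names_epoch(self):
        tr = train([1.0, 2.0], 0.0, 100.0)
        with pytest.raises(ValidationError, match="noxious"):
            net_evoked_rate(tr, Epoch("noxious", 50, 15), 120.0)

    def test_null_stationary_process_averages_to_zero(self, rng):
        """Homogeneous Poisson firing has zero net evoked rate in
        expectation (simulation oracle, 500 repeats)."""
        nets = []
        for _ in range(500):
            tr = poisson_train(3.0, 320.0, rng)
            nets.append(net_evoked_rate(tr, Epoch("noxious", 300, 15), 120.0))
        nets = np.array(nets)
        sem = nets.std(ddof=1) / np.sqrt(nets.size)
        assert abs(nets.mean()) < 3 * sem + 1e-12


class TestPsth:
    def test_counting(self):
        h = psth(train([0.2, 0.4, 1.5], 0.0, 2.0), Epoch("background", 0, 2), 1.0)
        np.testing.assert_array_equal(h.counts_per_bin, [2, 1])
        np.testing.assert_allclose(h.rate_per_bin, [2.0, 1.0])
        assert not h.partial_bin_dropped

    def test_empty_train_all_zero(self):
        h = psth(SpikeTrain(np.array([]), 0.0, 4.0),
                 Epoch("background", 0, 4), 1.0)
        assert h.counts_per_bin.sum() == 0

    def test_partial_bin_dropped_and_flagged(self):
        h = psth(train([0.1, 2.4], 0.0, 3.0), Epoch("background", 0, 2.5), 1.0)
        assert h.partial_bin_dropped
        assert h.bin_edges_s[-1] == 2.0
        assert h.counts_per_bin.sum() == 1  # 2.4 falls in the dropped bin

    def test_counts_conserve_total(self, rng):
        tr = bursty_random_train(rng)
        w = Epoch("background", 0, float(np.ceil(tr.t_stop)))
        h = psth(tr, w, 1.0)
        assert h.counts_per_bin.sum() == tr.n_spikes

    def test_bad_bin_width(self):
        with pytest.raises(ValidationError):
            psth(train([0.1]), Epoch("background", 0, 1), 0.0)


CRIT = BurstCriteria()


class TestBursts:
    def test_minimal_burst(self):
        tr = train([0.0, 0.5, 0.505, 0.9])
        (b,) = detect_bursts(tr, CRIT)
        assert (b.onset_s, b.n_spikes) == (0.5, 2)
        assert b.silent_period_s == pytest.approx(0.5)

    def test_short_silence_is_not_a_burst(self):
        assert detect_bursts(train([0.0, 0.05, 0.055]), CRIT) == []

    def test_burst_extends_over_consecutive_short_isis(self):
        (b,) = detect_bursts(train([0.0, 0.5, 0.505, 0.509, 0.7]), CRIT)
        assert (b.onset_s, b.n_spikes) == (0.5, 3)
        assert b.intra_isis_s == pytest.approx((0.005, 0.004))

    def test_first_spike_needs_observed_silence(self):
        # observed gap from t_start counts as silence ...
        assert len(detect_bursts(train([0.2, 0.205], 0.0, 1.0), CRIT)) == 1
        # ... but an insufficient observed gap does not
        assert detect_bursts(train([0.05, 0.055], 0.0, 1.0), CRIT) == []

    def test_matches_oracle_on_random_trains(self, rng):
        """Scan implementation is identical to an independent brute-force
        run-based scanner on 1000 random boundary-heavy trains."""
        for _ in range(1000):
            tr = bursty_random_train(rng)
            got = [(b.onset_s, b.n_spikes, b.silent_period_s)
                   for b in detect_bursts(tr, CRIT)]
            assert got == oracle_bursts(tr.timestamps, tr.t_start, CRIT)

    def test_matches_oracle_exhaustively_on_grid_trains(self):
        """Exhaustive equivalence over every train drawn from a fixed grid
        of timestamps straddling the 10 ms / 100 ms criterion boundaries."""
        grid = [0.0, 0.005, 0.010, 0.015, 0.020, 0.105, 0.115, 0.125,
                0.240, 0.360]
        n_checked = 0
        for k in range(2, 7):
            for ts in itertools.combinations(grid, k):
                tr = SpikeTrain(np.array(ts), -0.001, 1.0)
                got = [(b.onset_s, b.n_spikes, b.silent_period_s)
                       for b in detect_bursts(tr, CRIT)]
                assert got == oracle_bursts(ts, tr.t_start, CRIT)
                n_checked += 1
        assert n_checked == 837

    def test_burst_count_equals_flagged_pairs(self, rng):
        for _ in range(200):
            tr = bursty_random_train(rng)
            m = joint_isi_map(tr, CRIT)
            flagged = int(m["is_burst_start"].sum()) if len(m) else 0
            assert flagged == len(detect_bursts(tr, CRIT))

    def test_burst_rate_unit(self):
        bursts = [BurstEvent(10.0 * i, 2, 0.5, (0.005,)) for i in range(6)]
        ep = Epoch("background", 0, 300)
        assert burst_rate(bursts, ep) == pytest.approx(1.2)
        assert burst_rate([], ep) == 0.0
        ep2 = Epoch("background", 0, 600)
        assert burst_rate(bursts, ep2) == pytest.approx(0.6)


class TestJointIsiMap:
    def test_flag_rule(self):
        tr = train([0.0, 0.5, 0.505, 0.9])
        m = joint_isi_map(tr, CRIT, include_initial_gap=False)
        # pairs: (0.5, 0.005) flagged; (0.005, 0.395) not
        assert list(m["is_burst_start"]) == [True, False]

    def test_short_silence_not_flagged(self):
        tr = train([0.0, 0.05, 0.055, 0.5])
        m = joint_isi_map(tr, CRIT, include_initial_gap=False)
        assert not m["is_burst_start"].any()

    def test_too_few_spikes_gives_empty_map(self):
        assert len(joint_isi_map(train([0.1, 0.2]), CRIT)) == 0

    def test_initial_gap_entry(self):
        tr = train([0.2, 0.205, 0.9], 0.0)
        m = joint_isi_map(tr, CRIT)
        assert len(m) == 2
        assert m.loc[0, "isi1"] == pytest.approx(0.2)
        assert bool(m.loc[0, "is_burst_start"])


class TestCv2:
    def test_formula(self):
        tr = train([0.0, 0.1, 0.4])  # ISIs 0.1, 0.3
        s = cv2_series(tr)
        assert s.values[0] == pytest.approx(1.0)
        assert s.mean_isi[0] == pytest.approx(0.2)

    def test_regular_train_is_exactly_zero(self):
        tr = train(np.arange(200) * 0.25 + 0.125)
        assert cv2_series(tr).mean_cv2 == 0.0

    def test_undefined_below_three_spikes(self):
        assert cv2_series(train([0.1, 0.2])) is None

    @given(st.lists(st.floats(1e-3, 1e3), min_size=2, max_size=40))
    def test_bounds_and_scale_invariance(self, isis):
        ts = np.cumsum([0.5] + isis)
        s = cv2_series(SpikeTrain(ts, 0.0, float(ts[-1]) + 1))
        assert np.all(s.values >= 0) and np.all(s.values <= 2)
        s2 = cv2_series(SpikeTrain(ts * 7.5, 0.0, float(ts[-1]) * 7.5 + 1))
        np.testing.assert_allclose(s.values, s2.values, rtol=1e-6, atol=1e-9)

    def test_symmetry_in_the_pair(self):
        a = cv2_series(train([0.0, 0.1, 0.4])).values[0]
        b = cv2_series(train([0.0, 0.3, 0.4])).values[0]
        assert a == pytest.approx(b)

    def test_gamma_renewal_monotone_in_shape(self, rng):
        """More regular firing (larger gamma shape) gives lower mean CV2."""
        means = []
        for shape in [0.5, 1.0, 2.0, 4.0, 8.0]:
            isis = rng.gamma(shape, 1.0 / shape, 6000)
            ts = np.cumsum(isis)
            means.append(cv2_series(SpikeTrain(ts, 0.0, ts[-1] + 1)).mean_cv2)
        assert all(a > b for a, b in zip(means, means[1:]))


class TestSummarizeNeuron:
    def _record(self, rng):
        tr = poisson_train(3.0, 700.0, rng)
        eps = (Epoch("background", 0, 300, condition_tag="predrug"),
               Epoch("innocuous", 420, 15, 100.0, 6.0, "predrug"),
               Epoch("noxious", 630, 15, 500.0, 6.0, "predrug"))
        return NeuronRecord(train=tr, epochs=eps)

    def test_fields_match_primitive_metrics(self, rng):
        rec = self._record(rng)
        m = summarize_neuron(rec)["predrug"]
        assert m.background_hz == firing_rate(rec.train, rec.epochs[0])
        bg_train = rec.train.slice(0, 300)
        assert m.burst_rate_per_min == burst_rate(
            detect_bursts(bg_train), rec.epochs[0])
        assert m.n_isi_pairs == cv2_series(bg_train).n_pairs

    def test_translation_invariance(self, rng):
        rec = self._record(rng)
        shifted = NeuronRecord(
            train=rec.train.shift(10.0),
            epochs=tuple(Epoch(e.label, e.onset + 10.0, e.duration,
                               e.intensity_g, e.area_mm2, e.condition_tag)
                         for e in rec.epochs))
        a = summarize_neuron(rec)["predrug"]
        b = summarize_neuron(shifted)["predrug"]
        assert a.background_hz == pytest.approx(b.background_hz)
        assert a.net_noxious_hz == pytest.approx(b.net_noxious_hz)
        assert a.burst_rate_per_min == pytest.approx(b.burst_rate_per_min)
        assert (a.mean_cv2 is None) == (b.mean_cv2 is None)
        if a.mean_cv2 is not None:
            assert a.mean_cv2 == pytest.approx(b.mean_cv2)

    def test_missing_stimulus_epoch_names_neuron_and_condition(self, rng):
        rec = self._record(rng)
        partial = NeuronRecord(train=rec.train, epochs=rec.epochs[:2])
        with pytest.raises(ValidationError, match="noxious"):
            summarize_neuron(partial)

    def test_sparse_background_yields_undefined_cv2(self):
        tr = SpikeTrain(np.array([10.0, 500.0, 640.0]), 0.0, 700.0)
        eps = (Epoch("background", 0, 300, condition_tag="predrug"),
               Epoch("innocuous", 420, 15, condition_tag="predrug"),
               Epoch("noxious", 630, 15, condition_tag="predrug"))
        m = summarize_neuron(NeuronRecord(train=tr, epochs=eps))["predrug"]
        assert m.mean_cv2 is None and m.n_isi_pairs == 0
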