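"""Spike detection, spiking features, spike-train post-processing,
network features."""

import numpy as np
import pytest

from neurouq.features import (NetworkFeatures, SpikeTrainSet,
                              SpikingFeatures, binary_spike_postprocess,
                              find_spikes, network_features,
                              spiking_features, van_rossum_distance,
                              victor_purpura_distance)


def gaussian_bump(t, center, width=1.0, amplitude=80.0, baseline=-65.0):
    return baseline + amplitude * np.exp(-((t - center) / width)**2)


class TestFindSpikes:
    def test_flat_trace(self):
        t = np.linspace(0, 100, 1000)
        assert len(find_spikes(t, np.full_like(t, -65.0))) == 0

    def test_single_bump(self):
        t = np.linspace(0, 50, 5000)
        spikes = find_spikes(t, gaussian_bump(t, 25.0))
        assert len(spikes) == 1
        assert spikes[0].peak_time == pytest.approx(25.0, abs=0.02)
        assert spikes[0].peak_voltage == pytest.approx(15.0, abs=0.01)

    def test_two_bumps_ordered(self):
        t = np.linspace(0, 100, 10000)
        V = np.maximum(gaussian_bump(t, 30.0), gaussian_bump(t, 70.0))
        spikes = find_spikes(t, V)
        assert len(spikes) == 2
        assert spikes[0].peak_time < spikes[1].peak_time
        # windows never overlap
        assert spikes[0].time[-1] <= spikes[1].time[0] + 1e-12

    def test_window_contains_threshold_crossing(self):
        t = np.linspace(0, 50, 5000)
        spikes = find_spikes(t, gaussian_bump(t, 25.0), threshold=-30.0)
        s = spikes[0]
        assert s.V[s.onset_index] > -30.0
        assert s.V[max(s.onset_index - 1, 0)] <= -30.0 or s.onset_index == 0

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            find_spikes([0.0, 2.0, 1.0], [0.0, 0.0, 0.0])


class TestSpikingFeatures:
    def make_spikes(self, peak_times, t_end=2000.0):
        t = np.linspace(0, t_end, int(t_end * 10))
        V = np.full_like(t, -65.0)
        for pt in peak_times:
            V = np.maximum(V, gaussian_bump(t, pt))
        return find_spikes(t, V)

    def test_counts_and_rate(self):
        spikes = self.make_spikes([1100.0, 1200.0, 1300.0])
        info = {"stimulus_start": 1000.0, "stimulus_end": 1900.0}
        feats = spiking_features(spikes, info)
        assert feats["nr_spikes"] == 3
        assert feats["spike_rate"] == pytest.approx(3 / 900)
        assert feats["time_before_first_spike"] == pytest.approx(100.0, abs=0.1)

    def test_rate_times_duration_equals_count(self):
        spikes = self.make_spikes([1050.0, 1500.0])
        info = {"stimulus_start": 1000.0, "stimulus_end": 1900.0}
        feats = spiking_features(spikes, info)
        assert feats["spike_rate"] * 900 == pytest.approx(feats["nr_spikes"])

    def test_periodic_train_has_zero_accommodation(self):
        spikes = self.make_spikes([1100.0, 1200.0, 1300.0, 1400.0, 1500.0])
        feats = spiking_features(
            spikes, {"stimulus_start": 1000.0, "stimulus_end": 1900.0})
        assert feats["accommodation_index"] == pytest.approx(0.0, abs=1e-6)

    def test_missing_stimulus_key_rejected(self):
        spikes = self.make_spikes([1100.0])
        with pytest.raises(KeyError, match="stimulus_end"):
            spiking_features(spikes, {"stimulus_start": 0.0})

    def test_undefined_features_return_missing(self):
        spikes = self.make_spikes([1100.0])     # single spike
        feats = spiking_features(
            spikes, {"stimulus_start": 1000.0, "stimulus_end": 1900.0})
        assert feats["average_AHP_depth"] is None
        assert feats["accommodation_index"] is None
        assert feats["average_AP_overshoot"] == pytest.approx(15.0, abs=0.5)

    def test_triangular_ap_width_closed_form(self):
        # symmetric triangular spike of known slope: the half-height chord
        # can be computed analytically from the geometry
        dt = 0.01
        t = np.arange(0, 40, dt)
        V = np.full_like(t, -60.0)
        rise = 25.0                 # mV per ms on both flanks
        peak_t, peak_v = 20.0, 40.0
        tri = peak_v - rise * np.abs(t - peak_t)
        V = np.maximum(V, tri)
        spikes = find_spikes(t, V, threshold=-30.0)
        assert len(spikes) == 1
        s = spikes[0]
        v_half = 0.5 * (s.onset_voltage + s.peak_voltage)
        expected = 2 * (peak_v - v_half) / rise
        feats = spiking_features(
            spikes, {"stimulus_start": 0.0, "stimulus_end": 40.0})
        assert feats["average_AP_width"] == pytest.approx(expected, rel=1e-3)

    def test_ahp_depth_between_two_spikes(self):
        t = np.linspace(0, 3000, 30000)
        V = np.maximum(gaussian_bump(t, 1100.0), gaussian_bump(t, 1300.0))
        trough = V[(t > 1150) & (t < 1250)].min()
        spikes = find_spikes(t, V)
        feats = spiking_features(
            spikes, {"stimulus_start": 1000.0, "stimulus_end": 1900.0})
        assert feats["average_AHP_depth"] == pytest.approx(trough)


class TestBinaryPostprocess:
    def test_worked_example(self):
        trains = SpikeTrainSet([np.array([0.0, 2.0, 3.5])], end=4.0)
        grid, mat = binary_spike_postprocess(trains, dt=0.5)
        assert grid == pytest.approx(np.arange(0, 4.5, 0.5))
        assert mat.tolist() == [[1, 0, 0, 0, 1, 0, 0, 1, 0]]

    def test_empty_train(self):
        trains = SpikeTrainSet([np.array([])], end=4.0)
        _, mat = binary_spike_postprocess(trains, dt=0.5)
        assert np.all(mat == 0)

    def test_two_spikes_in_one_bin(self):
        trains = SpikeTrainSet([np.array([1.0, 1.1])], end=4.0)
        _, mat = binary_spike_postprocess(trains, dt=0.5)
        assert mat.sum() == 1

    def test_grid_length_and_count_bound(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 99.9, size=40))
        trains = SpikeTrainSet([spikes], end=100.0)
        grid, mat = binary_spike_postprocess(trains, dt=0.7)
        assert grid.size == int(np.floor(100.0 / 0.7)) + 1
        assert mat.sum() <= spikes.size

    def test_out_of_range_spike_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrainSet([np.array([5.0])], end=4.0)

    def test_text_round_trip(self, tmp_path):
        trains = SpikeTrainSet([np.array([0.0, 2.25]), np.array([])],
                               end=10.0)
        path = tmp_path / "trains.txt"
        trains.to_text(path)
        back = SpikeTrainSet.from_text(path)
        assert back.end == 10.0
        assert np.allclose(back.trains[0], trains.trains[0])
        assert back.trains[1].size == 0


class TestSpikeTrainDistances:
    def test_self_distance_zero(self):
        a = np.array([1.0, 5.0, 9.0])
        assert victor_purpura_distance(a, a) == 0.0
        assert van_rossum_distance(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_one_extra_spike_costs_one(self):
        a = np.array([1.0, 5.0])
        b = np.array([1.0, 5.0, 40.0])
        # the extra spike is far from everything: deleting it (cost 1)
        # is optimal for any move cost
        assert victor_purpura_distance(a, b, cost=1e6) == pytest.approx(1.0)
        assert victor_purpura_distance(a, b, cost=0.2) == pytest.approx(1.0)

    def test_symmetry_and_positivity(self):
        rng = np.random.default_rng(1)
        a = np.sort(rng.uniform(0, 100, 12))
        b = np.sort(rng.uniform(0, 100, 9))
        assert victor_purpura_distance(a, b) == victor_purpura_distance(b, a)
        assert victor_purpura_distance(a, b) > 0
        assert van_rossum_distance(a, b) == pytest.approx(
            van_rossum_distance(b, a))
        assert van_rossum_distance(a, b) > 0


class TestNetworkFeatures:
    def test_identical_regular_trains(self):
        train = np.arange(5.0, 995.0, 10.0)
        trains = SpikeTrainSet([train.copy() for _ in range(4)], end=1000.0)
        feats = network_features(trains, bin_width=5.0)
        assert feats["fanofactor"] == 0.0
        iu = np.triu_indices(4, k=1)
        assert feats["corrcoef"][iu] == pytest.approx(np.ones(6))
        assert feats["average_isi"] == pytest.approx(10.0)
        assert feats["average_local_variation"] == pytest.approx(0.0)

    def test_poisson_isi_statistics(self):
        rng = np.random.default_rng(8)
        rate = 0.1          # spikes per ms -> mean ISI 10 ms
        trains = []
        for _ in range(8):
            isi = rng.exponential(1 / rate, size=300)
            t = np.cumsum(isi)
            trains.append(t[t < 2000.0])
        ts = SpikeTrainSet(trains, end=2000.0)
        feats = network_features(ts, bin_width=10.0)
        assert feats["average_isi"] == pytest.approx(10.0, rel=0.05)
        assert feats["average_cv"] == pytest.approx(1.0, rel=0.05)
        assert feats["average_firing_rate"].mean() == pytest.approx(
            100.0, rel=0.05)

    def test_short_trains_get_missing_markers(self):
        ts = SpikeTrainSet([np.array([5.0]), np.array([1.0, 2.0, 3.0])],
                           end=10.0)
        feats = network_features(ts, bin_width=1.0)
        assert np.isnan(feats["cv"][0]) and np.isfinite(feats["cv"][1])

    def test_matrices_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(3)
        ts = SpikeTrainSet([np.sort(rng.uniform(0, 500, 30)) for _ in range(3)],
                           end=500.0)
        feats = network_features(ts, bin_width=5.0)
        for key in ("victor_purpura_dist", "van_rossum_dist", "corrcoef",
                    "covariance"):
            M = feats[key]
            assert np.allclose(M, M.T, equal_nan=True)
        assert np.allclose(np.diag(feats["corrcoef"]), 1.0)


class TestFeatureSets:
    def test_spiking_feature_set_on_trace(self):
        t = np.linspace(0, 2000, 20000)
        V = np.full_like(t, -65.0)
        for pt in (1100.0, 1200.0, 1300.0):
            V = np.maximum(V, gaussian_bump(t, pt))
        fs = SpikingFeatures()
        out = fs.calculate(t, V, {"stimulus_start": 1000.0,
                                  "stimulus_end": 1900.0})
        assert out["nr_spikes"][1] == 3
        assert out["average_AHP_depth"][1] == pytest.approx(-65.0, abs=0.5)

    def test_undefined_feature_marked_invalid(self):
        t = np.linspace(0, 2000, 20000)
        V = np.full_like(t, -65.0)          # no spikes at all
        fs = SpikingFeatures()
        out = fs.calculate(t, V, {"stimulus_start": 1000.0,
                                  "stimulus_end": 1900.0})
        assert out["average_AP_width"] == (None, None)
        assert out["nr_spikes"][1] == 0

    def test_network_feature_set(self):
        train = np.arange(5.0, 95.0, 10.0)
        ts = SpikeTrainSet([train, train + 1.0], end=100.0, resolution=0.5)
        fs = NetworkFeatures(features_to_run=["average_isi", "corrcoef"])
        out = fs.calculate(None, ts, None)
        assert out["average_isi"][1] == pytest.approx(10.0)
        assert out["corrcoef"][1].shape == (1,)


class TestPropertyBased:
    from hypothesis import given
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=99.9), max_size=30),
           st.floats(min_value=0.2, max_value=10.0))
    def test_binary_postprocess_invariants(self, spikes, dt):
        trains = SpikeTrainSet([np.sort(spikes)], end=100.0)
        grid, mat = binary_spike_postprocess(trains, dt=dt)
        assert grid.size == int(np.floor(100.0 / dt)) + 1
        assert mat.sum() <= len(spikes)
        if len(set(np.floor(np.array(spikes) / dt + 0.5))) == len(spikes):
            assert mat.sum() == len(spikes)   # distinct bins: one 1 per spike

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=0,
                    max_size=8),
           st.lists(st.floats(min_value=0, max_value=100), min_size=0,
                    max_size=8))
    def test_distances_nonnegative_and_symmetric(self, a, b):
        a, b = np.sort(a), np.sort(b)
        d_vp = victor_purpura_distance(a, b)
        d_vr = van_rossum_distance(a, b)
        assert d_vp >= 0 and d_vr >= -1e-12
        assert d_vp == pytest.approx(victor_purpura_distance(b, a))
        assert d_vr == pytest.approx(van_rossum_distance(b, a), abs=1e-9)
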