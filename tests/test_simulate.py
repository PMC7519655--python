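"""Simulator: arbors, coupled spike trains, and dual-stream rendering."""

import numpy as np
import pytest

from dualmea.detection import bandpass
from dualmea.geometry import ArrayParams, InvalidParameterError, build_hex_array
from dualmea.simulate import (
    Branch,
    GroundTruthNeuron,
    NetworkSpec,
    SpatialDecay,
    biphasic_waveform,
    generate_arbor,
    generate_network_spikes,
    neuron_hits,
    render_recording,
)

BOUNDS = (0.0, 1000.0, 0.0, 300.0)


class TestWaveform:
    def test_biphasic_negative_then_positive_unit_peak(self):
        t = np.arange(0, 1.40005, 1e-4)
        w = biphasic_waveform(t)
        assert w.min() == pytest.approx(-1.0, abs=1e-9)
        assert t[np.argmin(w)] < t[np.argmax(w)]
        assert 0.1 < w.max() < 1.0
        assert biphasic_waveform(-0.5) == 0.0 and biphasic_waveform(2.0) == 0.0


class TestGenerateArbor:
    def test_single_straight_branch_has_requested_velocity_and_length(self):
        rng = np.random.default_rng(0)
        n = generate_arbor(
            rng, BOUNDS, n_branches=1, velocity_range=(500.0, 500.0),
            length_range=(800.0, 800.0), direction_range=(0.0, 0.0),
            ais_position=(50.0, 150.0),
        )
        assert len(n.branches) == 1
        assert n.branches[0].velocity == 500.0
        assert n.branches[0].length == pytest.approx(800.0)

    def test_same_seed_reproduces_arbor(self):
        a = generate_arbor(np.random.default_rng(42), BOUNDS, n_branches=(1, 3))
        b = generate_arbor(np.random.default_rng(42), BOUNDS, n_branches=(1, 3))
        assert len(a.branches) == len(b.branches)
        for ba, bb in zip(a.branches, b.branches):
            assert np.array_equal(ba.points, bb.points)
            assert ba.velocity == bb.velocity

    def test_velocities_and_polylines_respect_ranges_and_bounds(self):
        rng = np.random.default_rng(1)
        vels = []
        for _ in range(300):
            n = generate_arbor(rng, BOUNDS, velocity_range=(300.0, 700.0))
            for br in n.branches:
                vels.append(br.velocity)
                assert (br.points[:, 0] >= BOUNDS[0] - 1e-9).all()
                assert (br.points[:, 0] <= BOUNDS[1] + 1e-9).all()
                assert (br.points[:, 1] >= BOUNDS[2] - 1e-9).all()
                assert (br.points[:, 1] <= BOUNDS[3] + 1e-9).all()
        assert 300.0 <= min(vels) and max(vels) <= 700.0

    def test_empty_bounds_and_bad_velocity_raise(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InvalidParameterError):
            generate_arbor(rng, (10.0, 10.0, 0.0, 5.0))
        with pytest.raises(InvalidParameterError):
            generate_arbor(rng, BOUNDS, velocity_range=(0.0, 100.0))


class TestNetworkSpikes:
    def test_deterministic_relay_shifts_train_by_latency(self):
        spec = NetworkSpec(
            n_neurons=2,
            firing_rate=np.array([5.0, 0.0]),
            connections=[(0, 1, 3.0, 1.0)],
            burst_rate=0.0,
            burst_gain=1.0,
        )
        trains = generate_network_spikes(spec, 100.0, np.random.default_rng(0))
        pre, post = trains[0], trains[1]
        keep = pre + 0.003 < 100.0
        assert np.allclose(post, pre[keep] + 0.003)

    def test_poisson_count_statistics_without_bursts(self):
        spec = NetworkSpec(n_neurons=1, firing_rate=5.0, burst_rate=0.0, burst_gain=1.0)
        trains = generate_network_spikes(spec, 100.0, np.random.default_rng(1))
        assert abs(len(trains[0]) - 500) < 3 * np.sqrt(500)

    def test_unit_gain_produces_flat_rate(self):
        spec = NetworkSpec(n_neurons=20, firing_rate=5.0, burst_rate=0.3, burst_gain=1.0)
        trains = generate_network_spikes(spec, 50.0, np.random.default_rng(2))
        counts = np.histogram(np.concatenate(list(trains.values())),
                              bins=np.arange(0, 51, 5))[0]
        # 20 x 5 Hz x 5 s = 500 expected per bin; no burst modulation
        assert (np.abs(counts - 500) < 5 * np.sqrt(500)).all()

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            NetworkSpec(connections=[(0, 1, 3.0, 1.5)])
        with pytest.raises(InvalidParameterError):
            NetworkSpec(connections=[(0, 1, -1.0, 0.5)])
        with pytest.raises(InvalidParameterError):
            generate_network_spikes(NetworkSpec(n_neurons=1), -1.0,
                                    np.random.default_rng(0))


@pytest.fixture(scope="module")
def soma_fixture():
    arr = build_hex_array(ArrayParams(8, 8, 18.0))
    ais_id = 3 * 8 + 3
    neuron = GroundTruthNeuron(0, arr.position(ais_id), [], soma_amplitude=-100.0)
    spikes = {0: np.array([0.1, 0.3, 0.7])}  # exact APS frame times
    return arr, ais_id, neuron, spikes


class TestRendering:
    def test_soma_peak_lands_at_spike_times_on_nearest_electrode(self, soma_fixture):
        arr, ais_id, neuron, spikes = soma_fixture
        rec, _ = render_recording([neuron], spikes, arr, noise=False, duration=1.0,
                                  rng=np.random.default_rng(0))
        trace = rec.aps_trace(ais_id)
        fs = rec.aps_params.sampling_rate
        assert trace.min() == pytest.approx(-100.0, rel=1e-5)
        for t in spikes[0]:
            k = int(round(t * fs))
            assert trace[k] == pytest.approx(-100.0, rel=1e-5)

    def test_noise_only_rms_in_ap_band_matches_mode_noise(self, small_array):
        rec, _ = render_recording(
            [], {}, small_array, duration=2.0, rng=np.random.default_rng(3)
        )
        filt = bandpass(rec.aps, (300.0, 5000.0), rec.aps_params.sampling_rate)
        rms = np.sqrt(np.mean(filt**2))
        assert rms == pytest.approx(10.4, rel=0.05)

    def test_axonal_arrival_latencies_match_path_distance_over_velocity(self):
        arr = build_hex_array(ArrayParams(12, 56, 18.0))
        ais = arr.position(6 * 56 + 2)
        br = Branch(np.array([ais, ais + [800.0, 0.0]]), velocity=500.0)
        neuron = GroundTruthNeuron(0, ais, [br])
        spikes = {0: np.array([0.2])}
        rec, gt = render_recording([neuron], spikes, arr, noise=False, duration=0.5,
                                   rng=np.random.default_rng(0))
        fs = rec.aps_params.sampling_rate
        hits = gt.hits[0]
        ax = hits[(hits["branch"] == 0) & (hits["s_um"] > 150)]
        for _, h in ax.iterrows():
            trace = rec.aps_trace(int(h["electrode"]))
            t_peak = np.argmin(trace) / fs
            t_expected = 0.2 + h["s_um"] / 500.0 * 1e-3
            assert abs(t_peak - t_expected) <= 0.5 / fs + 1e-9

    def test_same_seed_renders_bit_identical_recordings(self, soma_fixture):
        arr, ais_id, neuron, spikes = soma_fixture
        a, _ = render_recording([neuron], spikes, arr, sm_electrodes=[ais_id],
                                duration=1.0, rng=np.random.default_rng(7))
        b, _ = render_recording([neuron], spikes, arr, sm_electrodes=[ais_id],
                                duration=1.0, rng=np.random.default_rng(7))
        assert np.array_equal(a.aps, b.aps)
        assert np.array_equal(a.sm, b.sm)

    def test_overlapping_electrodes_carry_identical_signal_in_both_streams(
        self, soma_fixture
    ):
        arr, ais_id, neuron, spikes = soma_fixture
        rec, _ = render_recording([neuron], spikes, arr, sm_electrodes=[ais_id],
                                  duration=1.0, noise=False,
                                  rng=np.random.default_rng(0))
        # same continuous signal sampled at each stream's rate: compare peaks
        assert rec.sm_trace(ais_id).min() == pytest.approx(
            rec.aps_trace(ais_id).min(), rel=0.02
        )

    def test_out_of_bounds_neuron_warns_and_renders_partially(self, small_array):
        far = GroundTruthNeuron(0, (5000.0, 5000.0), [], soma_amplitude=-100.0)
        with pytest.warns(UserWarning, match="outside the array"):
            rec, _ = render_recording([far], {0: np.array([0.1])}, small_array,
                                      duration=0.3, noise=False,
                                      rng=np.random.default_rng(0))
        assert np.abs(rec.aps).max() == 0.0


class TestGroundTruthAttribution:
    def test_every_suprathreshold_sample_maps_to_a_hit(self, small_array):
        """With noise off, signal only appears on electrodes and times the
        ground-truth hit table predicts."""
        ais_id = 27
        neuron = GroundTruthNeuron(
            0, small_array.position(ais_id), [], soma_amplitude=-80.0
        )
        spikes = {0: np.array([0.1, 0.2])}
        rec, gt = render_recording([neuron], spikes, small_array, noise=False,
                                   duration=0.4, rng=np.random.default_rng(0))
        active = set(np.flatnonzero(np.abs(rec.aps).max(axis=1) > 0))
        listed = {small_array.index_of(e) for e in gt.hits[0]["electrode"]}
        assert active <= listed

    def test_amplitude_decay_is_monotone_and_peaks_at_ais(self, small_array):
        neuron = GroundTruthNeuron(
            0, small_array.position(27), [], soma_amplitude=-100.0
        )
        hits = neuron_hits(neuron, small_array, SpatialDecay())
        d = np.linalg.norm(
            small_array.positions[[small_array.index_of(e) for e in hits["electrode"]]]
            - neuron.ais_position,
            axis=1,
        )
        order = np.argsort(d)
        amps = hits["amplitude_uv"].to_numpy()[order]
        assert (np.diff(amps) <= 1e-9).all()
        assert hits["electrode"][int(np.argmax(hits["amplitude_uv"]))] == 27
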