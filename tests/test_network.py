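import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendelay.devices import DelayBank
from dendelay.network import (
    DendriticLayer,
    LIFParams,
    apply_delays,
    branch_current,
    coincidence_detect,
    forward,
    run_leaky_integrator,
    run_lif,
)
from dendelay.raster import SpikeRaster
from tests.conftest import random_raster


def shift_oracle(counts, offsets):
    """Spike-by-spike causal shift (the definition, one event at a time)."""
    n_ch, n_bins = counts.shape
    n_syn = offsets.shape[1]
    out = np.zeros((n_ch, n_syn, n_bins))
    for c in range(n_ch):
        for i in range(n_syn):
            for t in range(n_bins):
                tt = t + offsets[c, i]
                if tt < n_bins:
                    out[c, i, tt] += counts[c, t]
    return out


def lif_oracle(currents, params):
    """Scalar-loop LIF for one neuron's current trace."""
    alpha = params.alpha
    v = params.v_reset
    spikes, membrane = [], []
    for current in currents:
        v = alpha * v + current
        if v >= params.v_threshold:
            spikes.append(1.0)
            v = params.v_reset
        else:
            spikes.append(0.0)
        membrane.append(v)
    return np.array(spikes), np.array(membrane)


class TestApplyDelays:
    def test_zero_offsets_replicate_input(self, rng):
        raster = random_raster(rng, n_channels=2, n_bins=20)
        bank = DelayBank(np.zeros((2, 3)), dt=raster.dt)
        expanded = apply_delays(raster, bank)
        for i in range(3):
            np.testing.assert_array_equal(expanded[:, i, :], raster.counts)

    def test_single_spike_shift_and_horizon_drop(self):
        counts = np.zeros((1, 10), dtype=int)
        counts[0, 3] = 1
        raster = SpikeRaster(counts, 5e-3)
        bank = DelayBank(np.array([[0.020, 0.040]]), dt=5e-3)  # offsets 4, 8
        expanded = apply_delays(raster, bank)
        assert expanded[0, 0, 7] == 1 and expanded[0, 0].sum() == 1
        # spike at bin 3 + offset 8 -> bin 11, past the 10-bin horizon: dropped
        assert expanded[0, 1].sum() == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_matches_spikewise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        raster = random_raster(rng, n_channels=3, n_bins=25)
        delays = rng.uniform(0, 0.1, size=(3, 4))
        bank = DelayBank(delays, dt=raster.dt)
        np.testing.assert_array_equal(
            apply_delays(raster, bank), shift_oracle(raster.counts, bank.bin_offsets)
        )

    def test_dt_mismatch_rejected(self, rng):
        raster = random_raster(rng, n_channels=2, n_bins=10, dt=1e-3)
        bank = DelayBank(np.zeros((2, 2)), dt=5e-3)
        with pytest.raises(ValueError):
            apply_delays(raster, bank)


class TestBranchCurrent:
    def test_single_synapse_single_spike(self, small_bank):
        counts = np.zeros((2, 20), dtype=int)
        counts[0, 2] = 1
        expanded = apply_delays(SpikeRaster(counts, 5e-3), small_bank)
        weights = np.zeros((2, 4, 1))
        weights[0, 1, 0] = 0.7  # 35 ms -> offset 7
        layer = DendriticLayer(weights, small_bank)
        currents = branch_current(expanded, layer)
        assert currents[0, 9] == pytest.approx(0.7)
        assert np.count_nonzero(currents) == 1

    def test_coincident_superposition_and_linearity(self, small_bank, rng):
        raster = random_raster(rng, n_channels=2, n_bins=30)
        expanded = apply_delays(raster, small_bank)
        w = rng.normal(size=(2, 4, 3))
        layer = DendriticLayer(w, small_bank)
        layer2 = DendriticLayer(2 * w, small_bank)
        np.testing.assert_allclose(
            branch_current(expanded, layer2), 2 * branch_current(expanded, layer)
        )

    def test_weighted_spike_mass_conservation(self, small_bank, rng):
        raster = random_raster(rng, n_channels=2, n_bins=40)
        expanded = apply_delays(raster, small_bank)
        w = rng.normal(size=(2, 4, 2))
        currents = branch_current(expanded, DendriticLayer(w, small_bank))
        surviving = expanded.sum(axis=-1)  # spikes per (channel, synapse)
        expected = np.einsum("ci,cio->o", surviving, w)
        np.testing.assert_allclose(currents.sum(axis=-1), expected)

    def test_shape_mismatch_rejected(self, small_bank, rng):
        with pytest.raises(ValueError):
            branch_current(rng.normal(size=(2, 5, 10)), DendriticLayer(np.zeros((2, 4, 1)), small_bank))


class TestLIF:
    params = LIFParams(tau_mem=20e-3, v_threshold=1.0, v_reset=0.0, dt=5e-3)

    def test_zero_current_stays_at_reset(self):
        out = run_lif(np.zeros((2, 30)), self.params)
        assert out.spikes.sum() == 0
        np.testing.assert_array_equal(out.membrane, 0.0)

    def test_subthreshold_impulse_decays_geometrically(self):
        currents = np.zeros((1, 20))
        currents[0, 4] = 0.6
        out = run_lif(currents, self.params)
        t = np.arange(4, 20)
        np.testing.assert_allclose(
            out.membrane[0, 4:], 0.6 * self.params.alpha ** (t - 4), rtol=1e-12
        )
        assert out.spikes.sum() == 0

    def test_constant_suprathreshold_current_fires_periodically(self):
        currents = np.full((1, 60), 0.5)  # steady state 0.5/(1-alpha) > 1
        out = run_lif(currents, self.params)
        spikes, membrane = lif_oracle(currents[0], self.params)
        np.testing.assert_array_equal(out.spikes[0], spikes)
        np.testing.assert_allclose(out.membrane[0], membrane, rtol=1e-12)
        fire_bins = np.flatnonzero(spikes)
        assert len(fire_bins) > 2
        assert np.all(np.diff(fire_bins) == np.diff(fire_bins)[0])  # periodic

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_matches_scalar_oracle_on_random_currents(self, seed):
        rng = np.random.default_rng(seed)
        currents = rng.normal(0.2, 0.5, size=(3, 40))
        out = run_lif(currents, self.params)
        for o in range(3):
            spikes, membrane = lif_oracle(currents[o], self.params)
            np.testing.assert_array_equal(out.spikes[o], spikes)
            np.testing.assert_allclose(out.membrane[o], membrane, rtol=1e-10)

    def test_leaky_integrator_superposition_and_impulse(self, rng):
        a = rng.normal(size=(2, 30))
        b = rng.normal(size=(2, 30))
        np.testing.assert_allclose(
            run_leaky_integrator(a + b, self.params),
            run_leaky_integrator(a, self.params) + run_leaky_integrator(b, self.params),
            atol=1e-12,
        )
        impulse = np.zeros((1, 25))
        impulse[0, 3] = 2.0
        trace = run_leaky_integrator(impulse, self.params)
        t = np.arange(3, 25)
        np.testing.assert_allclose(trace[0, 3:], 2.0 * self.params.alpha ** (t - 3))
        assert trace[0, :3].sum() == 0.0


class TestForward:
    def test_ecg_and_multiclass_configs_produce_expected_shapes(self, rng):
        ecg_layer = DendriticLayer.initialize(2, 8, 1, seed=0)
        raster = random_raster(rng, n_channels=2, n_bins=50)
        out = forward(raster, ecg_layer, LIFParams(tau_mem=20e-3), readout="spiking")
        assert out.spikes.shape == (1, 50)
        multi = DendriticLayer.initialize(10, 16, 20, seed=1)
        raster2 = random_raster(rng, n_channels=10, n_bins=30)
        out2 = forward(raster2, multi, LIFParams(tau_mem=20e-3), readout="max_membrane")
        assert out2.membrane.shape == (20, 30)
        assert out2.spikes.sum() == 0

    def test_empty_raster_is_silent(self):
        layer = DendriticLayer.initialize(2, 4, 3, seed=0)
        raster = SpikeRaster(np.zeros((2, 20), dtype=int), 5e-3)
        out = forward(raster, layer, LIFParams(tau_mem=10e-3))
        assert out.spikes.sum() == 0 and np.all(out.membrane == 0)

    def test_time_translation_equivariance(self, rng):
        layer = DendriticLayer.initialize(3, 4, 2, seed=2)
        raster = random_raster(rng, n_channels=3, n_bins=30)
        padded = SpikeRaster(np.pad(raster.counts, ((0, 0), (0, 10))), raster.dt)
        shifted = padded.shift(6)
        out_base = forward(padded, layer, LIFParams(tau_mem=15e-3))
        out_shift = forward(shifted, layer, LIFParams(tau_mem=15e-3))
        np.testing.assert_allclose(
            out_shift.membrane[:, 6:], out_base.membrane[:, :-6], atol=1e-12
        )

    def test_causality(self, rng):
        layer = DendriticLayer.initialize(2, 3, 2, seed=3)
        raster = random_raster(rng, n_channels=2, n_bins=30)
        tampered = raster.counts.copy()
        tampered[:, 20:] += 3  # modify only the future
        out_a = forward(raster, layer, LIFParams(tau_mem=15e-3))
        out_b = forward(SpikeRaster(tampered, raster.dt), layer, LIFParams(tau_mem=15e-3))
        np.testing.assert_array_equal(out_a.membrane[:, :20], out_b.membrane[:, :20])
        np.testing.assert_array_equal(out_a.spikes[:, :20], out_b.spikes[:, :20])

    def test_zero_delay_single_synapse_reduces_to_plain_lif_layer(self, rng):
        n_ch, n_out, n_bins = 4, 3, 25
        raster = random_raster(rng, n_channels=n_ch, n_bins=n_bins)
        w = rng.normal(size=(n_ch, 1, n_out)) * 0.5
        bank = DelayBank(np.zeros((n_ch, 1)), dt=raster.dt)
        params = LIFParams(tau_mem=20e-3, dt=raster.dt)
        out = forward(raster, DendriticLayer(w, bank), params)
        plain_currents = np.einsum("co,ct->ot", w[:, 0, :], raster.counts.astype(float))
        ref = run_lif(plain_currents, params)
        np.testing.assert_allclose(out.membrane, ref.membrane, atol=1e-12)
        np.testing.assert_array_equal(out.spikes, ref.spikes)


class TestCoincidenceDetection:
    def _programmed_network(self, hot_index):
        # channel-1 delays as measured on four fabricated circuits; channel-2
        # passes through a near-zero delay reference synapse
        delays = np.array([[0.021, 0.035, 0.048, 0.058], [1e-9, 1e-9, 1e-9, 1e-9]])
        bank = DelayBank(delays, dt=5e-3)
        weights = np.full((2, 4, 1), 0.05)
        weights[0, hot_index, 0] = 1.0
        weights[1, 0, 0] = 1.0
        return DendriticLayer(weights, bank)

    def _two_spike_raster(self, lag_s, n_bins=40, dt=5e-3):
        counts = np.zeros((2, n_bins), dtype=int)
        counts[0, 0] = 1
        counts[1, int(round(lag_s / dt))] = 1
        return SpikeRaster(counts, dt)

    params = LIFParams(tau_mem=20e-3, v_threshold=1.8, dt=5e-3)

    def test_detects_lag_matching_programmed_delay(self):
        layer = self._programmed_network(hot_index=3)  # 58 ms
        result = coincidence_detect(self._two_spike_raster(0.058), layer, self.params)
        assert result["detected"]

    def test_misaligned_lag_stays_subthreshold(self):
        layer = self._programmed_network(hot_index=3)
        result = coincidence_detect(self._two_spike_raster(0.0), layer, self.params)
        assert not result["detected"]

    def test_peak_membrane_maximized_at_programmed_delay(self):
        layer = self._programmed_network(hot_index=3)
        lags = np.arange(0, 0.085, 0.005)
        peaks = [
            coincidence_detect(self._two_spike_raster(lag), layer, self.params)["peak_membrane"]
            for lag in lags
        ]
        assert lags[int(np.argmax(peaks))] == pytest.approx(0.058, abs=2.6e-3)

    def test_requires_two_channels(self, rng):
        layer = DendriticLayer.initialize(3, 2, 1, seed=0)
        with pytest.raises(ValueError):
            coincidence_detect(random_raster(rng, n_channels=3, n_bins=10), layer, self.params)
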