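"""Bouton model: spike influx, mass balance, simulation limits and the
per-event response statistics."""

import numpy as np
import pytest

from biospike.cell import (CellParams, CellState, SpikeTrain,
                           FluorescenceTrace, apply_spike,
                           calcium_derivatives, simulate, summary_stats,
                           transient_stats)


class TestSpikeInflux:
    def test_buffer_partition(self, toy_sensor, bouton):
        st = CellState.resting(bouton, toy_sensor)
        new = apply_spike(st, a_ca=41.0, kappa_b=40.0)
        assert new.ca_free - st.ca_free == pytest.approx(1.0)
        assert new.b_ca - st.b_ca == pytest.approx(40.0)

    def test_no_buffer(self, toy_sensor, bouton):
        st = CellState.resting(bouton, toy_sensor)
        new = apply_spike(st, a_ca=5.0, kappa_b=0.0)
        assert new.ca_free - st.ca_free == pytest.approx(5.0)
        assert new.b_ca == st.b_ca

    @pytest.mark.parametrize("kappa", [0.3, 7.0, 40.0, 150.0])
    def test_total_increment_conserved(self, toy_sensor, bouton, kappa):
        st = CellState.resting(bouton, toy_sensor)
        new = apply_spike(st, a_ca=13.0, kappa_b=kappa)
        gained = (new.ca_free - st.ca_free) + (new.b_ca - st.b_ca)
        assert gained == pytest.approx(13.0)


class TestDerivatives:
    def test_resting_state_is_fixed_point(self, toy_sensor, bouton):
        st = CellState.resting(bouton, toy_sensor)
        d = calcium_derivatives(st, bouton, toy_sensor)
        assert abs(d["ca_free"]) < 1e-9
        assert abs(d["ca_slow"]) < 1e-9
        assert abs(d["ca_store"]) < 1e-9

    def test_pump_saturates(self, toy_sensor, bouton):
        # far above pump_km the extrusion flux approaches pump_vmax:
        # compare the free-calcium derivative at two calcium levels
        st = CellState.resting(bouton, toy_sensor)
        quiet = bouton.replace(store_in_vmax=0.0, store_out_vmax=0.0,
                               slow_k=0.0, g_total=0.0)
        hi = CellState(ca_free=100 * quiet.pump_km, ca_slow=st.ca_slow,
                       b_ca=st.b_ca, ca_store=st.ca_store,
                       sensor=st.sensor)
        d = calcium_derivatives(hi, quiet, toy_sensor)
        beta = 1.0 + quiet.kappa_b
        expected = -(quiet.pump_vmax * 100 / 101 - quiet.leak()) / beta
        assert d["ca_free"] == pytest.approx(expected, rel=1e-9)

    def test_conservation_with_transport_disabled(self, toy_sensor):
        # pumps, leak and store off: total calcium constant over 1 s
        cell = CellParams(pump_vmax=0.0, store_in_vmax=0.0,
                          store_out_vmax=0.0, sigma=0.0)
        spikes = SpikeTrain(np.array([0.05]))
        _, lat = simulate(cell, toy_sensor, spikes, 1.0, 1000.0,
                          return_latents=True)
        from biospike._kernels import bound_lobes
        beta = 1.0 + cell.kappa_b
        r = cell.slow_frac / (1.0 - cell.slow_frac)
        totals = []
        for i in range(lat["ca_free"].size):
            bound = bound_lobes(lat["occupancy"][i])
            totals.append(beta * lat["ca_free"][i]
                          + cell.g_total * toy_sensor.n_ca_per_lobe * bound
                          + lat["ca_store"][i] + r * lat["ca_slow"][i])
        totals = np.array(totals)
        # before the spike and after it, totals are each constant
        assert np.ptp(totals[:40]) < 1e-7
        assert np.ptp(totals[60:]) < 1e-7
        assert totals[-1] - totals[0] == pytest.approx(cell.a_ca, rel=1e-6)


class TestSimulate:
    def test_no_spikes_flat_zero(self, toy_sensor, bouton):
        tr = simulate(bouton.replace(sigma=0.0), toy_sensor,
                      SpikeTrain(np.empty(0)), 0.5, 1000.0)
        assert np.abs(tr.dff).max() < 1e-9

    def test_deterministic_given_seed(self, toy_sensor, bouton):
        cell = bouton.replace(sigma=0.05)
        a = simulate(cell, toy_sensor, SpikeTrain(np.array([0.1])), 0.5,
                     1000.0, noise_seed=11)
        b = simulate(cell, toy_sensor, SpikeTrain(np.array([0.1])), 0.5,
                     1000.0, noise_seed=11)
        assert np.array_equal(a.dff, b.dff)

    def test_spike_outside_window_rejected(self, toy_sensor, bouton):
        with pytest.raises(ValueError):
            simulate(bouton, toy_sensor, SpikeTrain(np.array([2.0])), 1.0)

    def test_two_spike_linearity_in_small_signal_limit(self, toy_sensor,
                                                       bouton):
        # a_ca -> 0 with a far-subsaturating sensor: responses to two
        # spikes 500 ms apart sum linearly within 2%
        cell = bouton.replace(a_ca=0.5, sigma=0.0)
        one = simulate(cell, toy_sensor, SpikeTrain(np.array([0.1])), 1.2,
                       1000.0)
        two = simulate(cell, toy_sensor, SpikeTrain(np.array([0.1, 0.6])),
                       1.2, 1000.0)
        shifted = np.zeros_like(one.dff)
        shifted[500:] = one.dff[:one.dff.size - 500]
        lin = one.dff + shifted
        peak2 = two.dff[600:].max()
        peak_lin = lin[600:].max()
        assert peak2 == pytest.approx(peak_lin, rel=0.02)


class TestSummaryStats:
    def test_exponential_half_decay(self):
        tau = 0.05
        t = np.arange(0, 1.0, 1e-3)
        y = np.zeros_like(t)
        y[100:] = np.exp(-(t[100:] - 0.1) / tau)
        trace = FluorescenceTrace(t=t, dff=y, rate=1000.0)
        st = transient_stats(trace, 0.1)
        assert st["half_decay"] == pytest.approx(tau * np.log(2), rel=0.02)

    def test_linear_ramp_rise_time(self):
        t = np.arange(0, 0.1, 1e-3)
        y = np.clip((t - 0.02) / 0.01, 0, 1) * np.where(t < 0.03, 1, 1)
        # ramp 0 -> 1 over 10 ms starting at 20 ms
        y = np.clip((t - 0.02) / 0.01, 0.0, 1.0)
        trace = FluorescenceTrace(t=t, dff=y, rate=1000.0)
        st = transient_stats(trace, 0.02)
        assert st["rise_10_90"] == pytest.approx(0.008, rel=0.02)

    def test_biexponential_half_decay_matches_root_finding(self):
        from scipy.optimize import brentq
        w1, w2, t1_, t2_ = 0.6, 0.4, 0.02, 0.2
        t = np.arange(0, 2.0, 1e-3)
        y = np.zeros_like(t)
        mask = t >= 0.1
        y[mask] = w1 * np.exp(-(t[mask] - 0.1) / t1_) \
            + w2 * np.exp(-(t[mask] - 0.1) / t2_)
        trace = FluorescenceTrace(t=t, dff=y, rate=1000.0)
        st = transient_stats(trace, 0.1)
        f = lambda x: w1 * np.exp(-x / t1_) + w2 * np.exp(-x / t2_) - 0.5
        expected = brentq(f, 1e-6, 1.9)
        assert st["half_decay"] == pytest.approx(expected, abs=1.5e-3)

    def test_event_at_edge_reported_undefined(self, toy_sensor, bouton):
        tr = simulate(bouton.replace(sigma=0.0), toy_sensor,
                      SpikeTrain(np.array([0.45])), 0.5, 1000.0)
        ev = summary_stats(tr, SpikeTrain(np.array([0.45])))
        assert ev[0]["half_decay"] is None

    def test_snr_uses_robust_baseline_sd(self, toy_sensor, bouton, rng):
        cell = bouton.replace(sigma=0.02)
        spikes = SpikeTrain(np.array([0.3]))
        tr = simulate(cell, toy_sensor, spikes, 0.8, 1000.0, noise_seed=5)
        ev = summary_stats(tr, spikes, baseline_window=0.25)
        assert ev[0]["snr"] == pytest.approx(ev[0]["peak"] / 0.02, rel=0.5)


class TestTrainResponse:
    def test_use_dependent_slowing_emerges(self, jgcamp8f, gcamp6f,
                                           bouton):
        from biospike.cell import slice_statistics
        st8 = slice_statistics(bouton, jgcamp8f)
        st6 = slice_statistics(bouton, gcamp6f)
        r8 = st8["half_decay_10_ms"] / st8["half_decay_1_ms"]
        r6 = st6["half_decay_10_ms"] / st6["half_decay_1_ms"]
        assert r8 > 2.0
        assert 1.2 < r6 < 2.2
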