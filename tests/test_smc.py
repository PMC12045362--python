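"""Particle-Gibbs spike inference: observation model, conditional SMC,
parameter updates, MAP extraction, and the linear AR(2) baseline."""

import numpy as np
import pytest
from scipy import stats

from biospike.cell import (CellParams, FluorescenceTrace, SpikeTrain,
                           simulate, default_cell)
from biospike.smc import (InferenceConfig, LatentTrajectory, pgas_infer,
                          map_spikes, conditional_smc, update_parameters,
                          log_likelihood, _BioModel, fit_ar2_kernel,
                          PARAM_NAMES)
from biospike.synthetic import TracePreset, generate_trace
from biospike.metrics import match_spikes, classification_metrics
from biospike import _kernels as _k


class TestLogLikelihood:
    def test_gaussian_mode(self):
        ll = log_likelihood(0.3, 0.3, 0.0, 0.1)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * 0.01))

    def test_symmetry(self):
        up = log_likelihood(0.3 + 0.05, 0.3, 0.0, 0.1)
        dn = log_likelihood(0.3 - 0.05, 0.3, 0.0, 0.1)
        assert up == pytest.approx(dn)

    def test_matches_dense_gaussian_logpdf(self, rng):
        y = rng.normal(0, 1, 200)
        pred = rng.normal(0, 1, 200)
        base = rng.normal(0, 0.1, 200)
        ll = log_likelihood(y, pred, base, 0.17)
        ref = stats.norm.logpdf(y, loc=pred + base, scale=0.17).sum()
        assert ll == pytest.approx(ref)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(0.0, 0.0, 0.0, 0.0)


@pytest.fixture(scope="module")
def single_spike_setup(request):
    sensor = request.getfixturevalue("jgcamp8f")
    cell = default_cell().replace(sigma=0.0)
    trace = simulate(cell, sensor, SpikeTrain(np.array([0.4])), 1.0,
                     1000.0)
    return sensor, cell, trace


class TestConditionalSMC:
    def test_low_noise_single_spike_recovery(self, single_spike_setup):
        sensor, cell, trace = single_spike_setup
        model = _BioModel(sensor, cell, trace.dt, 256)
        theta = dict(a_ca=cell.a_ca, g_total=cell.g_total,
                     pump_vmax=cell.pump_vmax, R_f=sensor.R_f,
                     sigma=1e-3, rate=5.0, sigma_drift=1e-3)
        cfg = InferenceConfig(n_particles=64, seed=0)
        rng = np.random.default_rng(0)
        traj = None
        hits = 0
        total = 0
        for it in range(60):
            traj = conditional_smc(trace, theta, model, traj, cfg, rng)
            if it >= 10:
                bins = np.nonzero(traj.spikes)[0]
                total += 1
                # data convention: the spike's effect appears one sample
                # after the 400 ms bin
                hits += int(bins.size >= 1
                            and np.abs(bins - 400).min() <= 1)
        assert hits / total >= 0.95

    def test_flat_trace_stays_empty(self, jgcamp8f):
        cell = default_cell().replace(sigma=0.0)
        trace = simulate(cell, jgcamp8f, SpikeTrain(np.empty(0)), 1.0,
                         1000.0)
        model = _BioModel(jgcamp8f, cell, trace.dt, 256)
        theta = dict(a_ca=cell.a_ca, g_total=cell.g_total,
                     pump_vmax=cell.pump_vmax, R_f=jgcamp8f.R_f,
                     sigma=1e-3, rate=2.0, sigma_drift=1e-3)
        cfg = InferenceConfig(n_particles=32, seed=0)
        rng = np.random.default_rng(1)
        traj = None
        empty = 0
        for _ in range(30):
            traj = conditional_smc(trace, theta, model, traj, cfg, rng)
            empty += int(traj.spikes.sum() == 0)
        assert empty >= 29

    def test_reference_length_mismatch_rejected(self, single_spike_setup):
        sensor, cell, trace = single_spike_setup
        model = _BioModel(sensor, cell, trace.dt, 64)
        theta = dict(a_ca=cell.a_ca, g_total=cell.g_total,
                     pump_vmax=cell.pump_vmax, R_f=sensor.R_f,
                     sigma=0.1, rate=5.0, sigma_drift=0.01)
        bad = LatentTrajectory(np.zeros(10), np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            conditional_smc(trace, theta, model, bad,
                            InferenceConfig(n_particles=8, seed=0),
                            np.random.default_rng(0))


class TestUpdateParameters:
    def _setup(self, jgcamp8f):
        cell = default_cell().replace(sigma=0.0)
        trace = simulate(cell, jgcamp8f, SpikeTrain(np.array([0.2])), 0.5,
                         500.0)
        model = _BioModel(jgcamp8f, cell, trace.dt, 128)
        n = trace.dff.size
        traj = LatentTrajectory(np.zeros(n), np.zeros(n), np.zeros(n))
        traj.spikes[100] = 1
        theta = dict(a_ca=cell.a_ca, g_total=cell.g_total,
                     pump_vmax=cell.pump_vmax, R_f=jgcamp8f.R_f,
                     sigma=0.05, rate=5.0, sigma_drift=0.01)
        centers = dict(theta)
        return trace, traj, theta, model, centers

    def test_zero_proposal_scale_is_identity(self, jgcamp8f):
        trace, traj, theta, model, centers = self._setup(jgcamp8f)
        cfg = InferenceConfig(n_particles=8, seed=0)
        cfg.proposal_scales = {k: 0.0 for k in PARAM_NAMES}
        new, _ = update_parameters(trace, traj, theta, model, cfg,
                                   centers, np.random.default_rng(0))
        assert new == theta

    def test_flat_likelihood_recovers_prior(self, jgcamp8f):
        # with a huge observation sigma the conditional posterior of a_ca
        # is its prior; the MH chain should match it (KS test)
        trace, traj, theta, model, centers = self._setup(jgcamp8f)
        theta = dict(theta, sigma=1e6)
        cfg = InferenceConfig(n_particles=8, seed=0)
        cfg.proposal_scales = {k: (0.8 if k == "a_ca" else 0.0)
                               for k in PARAM_NAMES}
        rng = np.random.default_rng(7)
        n_draws = 4000
        draws = np.empty(n_draws)
        th = dict(theta)
        for i in range(n_draws):
            th, _ = update_parameters(trace, traj, th, model, cfg,
                                      centers, rng)
            draws[i] = th["a_ca"]
        # thin the chain so the KS comparison sees near-independent draws
        thinned = np.log(draws[400::15])
        sd = cfg.prior_sd["a_ca"]
        ref = np.log(centers["a_ca"]) \
            + sd * np.random.default_rng(1).standard_normal(4000)
        assert stats.ks_2samp(thinned, ref).pvalue > 0.01

    def test_log_posterior_finite(self, jgcamp8f):
        trace, traj, theta, model, centers = self._setup(jgcamp8f)
        cfg = InferenceConfig(n_particles=8, seed=0)
        rng = np.random.default_rng(3)
        th = dict(theta)
        for _ in range(200):
            th, lp = update_parameters(trace, traj, th, model, cfg,
                                       centers, rng)
            assert np.isfinite(lp)


class TestMapSpikes:
    def test_all_zero(self):
        assert len(map_spikes(np.zeros(100), 0.001)) == 0

    def test_single_bin(self):
        prob = np.zeros(100)
        prob[40] = 0.9
        out = map_spikes(prob, 0.001)
        assert len(out) == 1
        assert out.times[0] == pytest.approx(0.0405)

    def test_adjacent_bins_merge_at_weighted_centroid(self):
        prob = np.zeros(100)
        prob[40] = 0.6
        prob[41] = 0.8
        out = map_spikes(prob, 0.001)
        assert len(out) == 1
        expected = ((40 * 0.6 + 41 * 0.8) / 1.4 + 0.5) * 0.001
        assert out.times[0] == pytest.approx(expected)

    def test_times_strictly_increasing(self, rng):
        prob = rng.random(500)
        out = map_spikes(prob, 0.002)
        assert np.all(np.diff(out.times) > 0)


class TestEndToEnd:
    def test_seeded_determinism(self, jgcamp8f):
        preset = TracePreset(duration=3.0, sigma=0.1, drift_amp=0.02)
        trace, spikes, _ = generate_trace(preset, jgcamp8f, seed=2)
        cfg = dict(n_particles=24, n_iterations=8, seed=5)
        a = pgas_infer(trace, jgcamp8f, InferenceConfig(**cfg))
        b = pgas_infer(trace, jgcamp8f, InferenceConfig(**cfg))
        assert np.array_equal(a.spike_prob, b.spike_prob)
        assert np.array_equal(a.map_spikes.times, b.map_spikes.times)
        for k in a.param_samples:
            assert np.array_equal(a.param_samples[k], b.param_samples[k])

    def test_spike_probabilities_valid(self, jgcamp8f):
        preset = TracePreset(duration=2.0, sigma=0.1)
        trace, spikes, _ = generate_trace(preset, jgcamp8f, seed=4)
        post = pgas_infer(trace, jgcamp8f,
                          InferenceConfig(n_particles=24, n_iterations=8,
                                          seed=0))
        assert post.spike_prob.min() >= 0.0
        assert post.spike_prob.max() <= 1.0
        assert np.all(np.diff(post.map_spikes.times) > 0)


class TestLinearAR:
    def test_kernel_impulse_response_matches_closed_form(self, jgcamp8f):
        dt = 1e-3
        g1, g2, amp = fit_ar2_kernel(jgcamp8f, default_cell(), dt)
        # closed-form AR(2) impulse response from the poles
        disc = np.sqrt(g1 * g1 + 4 * g2 + 0j)
        p1 = (g1 + disc) / 2
        p2 = (g1 - disc) / 2
        n = 50
        h = np.real((p1 ** np.arange(1, n + 1)
                     - p2 ** np.arange(1, n + 1)) / (p1 - p2))
        c1 = c2 = 0.0
        sim = []
        for t in range(n):
            c = g1 * c1 + g2 * c2 + (1.0 if t == 0 else 0.0)
            sim.append(c)
            c2, c1 = c1, c
        assert np.allclose(sim, h, atol=1e-10)

    def test_linear_model_self_consistency(self, jgcamp8f):
        # a single-spike trace generated by the AR model itself is
        # recovered by linear-model inference
        dt = 1e-3
        g1, g2, amp = fit_ar2_kernel(jgcamp8f, default_cell(), dt)
        n = 800
        s = np.zeros(n)
        s[300] = 1
        c = _k.path_predict_lin(s.astype(np.int64), np.zeros(n), g1, g2,
                                amp, 0.0)
        rng = np.random.default_rng(0)
        y = c + rng.normal(0, 0.05, n)
        trace = FluorescenceTrace(t=np.arange(n) * dt, dff=y, rate=1000.0)
        cfg = InferenceConfig(n_particles=32, n_iterations=12, seed=1,
                              generative_model="linear_ar")
        post = pgas_infer(trace, jgcamp8f, cfg)
        assert len(post.map_spikes) >= 1
        assert np.abs(post.map_spikes.times - 0.300).min() < 0.010
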