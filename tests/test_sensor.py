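"""Sensor kinetics: on-rate law, generator structure, steady states,
master-equation propagation and state classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from biospike.sensor import (LobeKinetics, SensorModel, SensorState,
                             build_generator, steady_state, fluorescence,
                             dff, propagate, classify_states,
                             lobe_on_rate, saturating_state)


def lobe(**kw):
    base = dict(k_off_ca=100.0, K_a=0.2, H=1.0, k_on_pep=500.0,
                k_off_pep=20.0)
    base.update(kw)
    return LobeKinetics(**base)


class TestOnRate:
    @pytest.mark.parametrize("koff,Ka,H,ca,expected", [
        (100.0, 0.2, 1.0, 0.2, 100.0),   # ca = K_a forces k_on = k_off
        (100.0, 0.2, 1.0, 0.0, 0.0),
        (50.0, 1.0, 2.0, 2.0, 200.0),    # 50 * 2**2
    ])
    def test_values(self, koff, Ka, H, ca, expected):
        lb = lobe(k_off_ca=koff, K_a=Ka, H=H)
        assert lobe_on_rate(lb, ca) == pytest.approx(expected)

    def test_strictly_increasing(self):
        lb = lobe(H=1.7)
        cas = np.linspace(0.01, 10, 50)
        rates = [lobe_on_rate(lb, c) for c in cas]
        assert np.all(np.diff(rates) > 0)

    def test_negative_ca_rejected(self):
        with pytest.raises(ValueError):
            lobe_on_rate(lobe(), -0.1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            lobe(k_off_ca=-1.0)
        with pytest.raises(ValueError):
            lobe(H=5.0)


class TestGenerator:
    @pytest.mark.parametrize("ca", [0.0, 0.05, 1.0, 50.0])
    def test_columns_conserve_probability(self, toy_sensor, ca):
        G = build_generator(toy_sensor, ca)
        assert np.abs(G.sum(axis=0)).max() < 1e-12

    def test_off_diagonal_nonnegative(self, toy_sensor):
        G = build_generator(toy_sensor, 0.7)
        off = G - np.diag(np.diag(G))
        assert (off >= 0).all()

    def test_only_single_lobe_single_step_transitions(self, toy_sensor):
        G = build_generator(toy_sensor, 1.0)
        for to in range(9):
            for fr in range(9):
                if to == fr or G[to, fr] == 0:
                    continue
                dn = abs(to // 3 - fr // 3)
                dc = abs(to % 3 - fr % 3)
                assert sorted([dn, dc]) == [0, 1]

    def test_zero_calcium_stationary_is_all_apo(self, toy_sensor):
        st = steady_state(toy_sensor, 0.0)
        assert st.occupancy[0, 0] == pytest.approx(1.0)

    def test_duplicated_lobe_marginal_matches_3state_chain(self):
        lb = lobe()
        sensor = SensorModel(lobe_N=lb, lobe_C=lb, R_f=10.0)
        ca = 0.5
        n = 400
        dt = 1e-3
        states = propagate(sensor, SensorState.all_apo(),
                           np.full(n, ca), dt)
        # oracle: dense matrix exponential of the single-lobe chain
        G3 = lb.generator(ca)
        pN = expm(G3 * dt * (n - 1)) @ np.array([1.0, 0.0, 0.0])
        marginal = states[-1].occupancy.sum(axis=1)
        assert np.abs(marginal - pN).max() < 1e-8


class TestSteadyState:
    def test_matches_long_time_integration(self, toy_sensor):
        ca = 1.0
        target = steady_state(toy_sensor, ca).vector
        # long-time oracle from two different starting states
        for start in (SensorState.all_apo(), saturating_state(toy_sensor)):
            states = propagate(toy_sensor, start, np.full(3000, ca), 5e-3)
            assert np.abs(states[-1].vector - target).max() < 1e-8

    def test_fluorescent_occupancy_monotone_in_calcium(self, toy_sensor):
        grid = np.linspace(0.0, 10.0, 30)
        phi = [steady_state(toy_sensor, c).fluorescent_fraction
               for c in grid]
        assert np.all(np.diff(phi) >= -1e-12)

    def test_continuity_in_ca(self, toy_sensor):
        a = steady_state(toy_sensor, 1.0).vector
        b = steady_state(toy_sensor, 1.0 + 1e-7).vector
        assert np.abs(a - b).max() < 1e-5


class TestFluorescence:
    def test_cell_mode_anchors(self, toy_sensor):
        z = steady_state(toy_sensor, 0.0)
        assert fluorescence(z, toy_sensor, "cell") == pytest.approx(1.0)
        sat = saturating_state(toy_sensor)
        assert fluorescence(sat, toy_sensor, "cell") == pytest.approx(
            toy_sensor.R_f)

    def test_stopped_flow_mode_range(self, toy_sensor):
        mid = steady_state(toy_sensor, 0.3)
        f = fluorescence(mid, toy_sensor, "stopped_flow")
        assert 0.0 < f < 1.0

    def test_midway_state_linear_scaling(self, toy_sensor):
        sensor = SensorModel(lobe_N=toy_sensor.lobe_N,
                             lobe_C=toy_sensor.lobe_C, R_f=5.0)
        z = steady_state(sensor, 0.0).fluorescent_fraction
        s = saturating_state(sensor).fluorescent_fraction
        # construct a state with phi exactly midway
        target_phi = 0.5 * (z + s)
        lo, hi = 0.0, 1e3
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            phi = steady_state(sensor, mid).fluorescent_fraction
            if phi < target_phi:
                lo = mid
            else:
                hi = mid
        state = steady_state(sensor, 0.5 * (lo + hi))
        assert fluorescence(state, sensor, "cell") == pytest.approx(3.0,
                                                                    abs=1e-5)

    def test_dff(self):
        assert dff(2.0, 1.0) == pytest.approx(1.0)
        assert dff(3.7, 3.7) == 0.0
        with pytest.raises(ValueError):
            dff(1.0, 0.0)


class TestPropagate:
    def test_constant_ca_reaches_steady_state(self, toy_sensor):
        ca = 0.8
        states = propagate(toy_sensor, SensorState.all_apo(),
                           np.full(4000, ca), 5e-3)
        assert np.abs(states[-1].vector
                      - steady_state(toy_sensor, ca).vector).max() < 1e-7

    def test_occupancy_sum_conserved(self, toy_sensor, rng):
        ca = rng.uniform(0, 5, size=2000)
        states = propagate(toy_sensor, SensorState.all_apo(), ca, 1e-3)
        sums = np.array([s.occupancy.sum() for s in states])
        assert np.abs(sums - 1.0).max() < 1e-8

    def test_matches_matrix_exponential_for_random_sensors(self, rng):
        # oracle equivalence on constant calcium
        for _ in range(20):
            lb_n = lobe(k_off_ca=float(rng.uniform(10, 2000)),
                        K_a=float(rng.uniform(0.05, 5)),
                        H=float(rng.uniform(0.7, 2.5)),
                        k_on_pep=float(rng.uniform(10, 5000)),
                        k_off_pep=float(rng.uniform(1, 500)))
            lb_c = lobe(k_off_ca=float(rng.uniform(1, 200)),
                        K_a=float(rng.uniform(0.1, 10)),
                        H=float(rng.uniform(0.7, 2.5)),
                        k_on_pep=float(rng.uniform(5, 1000)),
                        k_off_pep=float(rng.uniform(0.5, 100)))
            sensor = SensorModel(lobe_N=lb_n, lobe_C=lb_c, R_f=10.0)
            ca = float(rng.uniform(0, 10))
            n = 50
            dt = 2e-3
            states = propagate(sensor, SensorState.all_apo(),
                               np.full(n, ca), dt)
            ref = expm(build_generator(sensor, ca) * dt * (n - 1)) \
                @ SensorState.all_apo().vector
            assert np.abs(states[-1].vector - ref).max() < 1e-7

    def test_stiff_rate_ratios_stable(self):
        fast = lobe(k_off_ca=5000.0, k_on_pep=20000.0, k_off_pep=2000.0)
        slow = lobe(k_off_ca=0.005, k_on_pep=0.05, k_off_pep=0.002)
        sensor = SensorModel(lobe_N=fast, lobe_C=slow, R_f=10.0)
        states = propagate(sensor, SensorState.all_apo(),
                           np.full(200, 1.0), 1e-3)
        v = states[-1].vector
        assert np.isfinite(v).all() and v.min() >= -1e-12

    def test_single_lobe_limit_matches_two_state_kinetics(self):
        # remove the peptide step and freeze the C lobe: the fluorescent...
        # apo<->Ca chain relaxes as a single exponential with rate
        # k_on + k_off
        lb = LobeKinetics(k_off_ca=100.0, K_a=0.2, H=1.0,
                          k_on_pep=1e-9, k_off_pep=1e3)
        frozen = LobeKinetics(k_off_ca=1e-9, K_a=1e9, H=1.0,
                              k_on_pep=1e-9, k_off_pep=1e3)
        sensor = SensorModel(lobe_N=lb, lobe_C=frozen, R_f=10.0)
        ca = 0.4
        kon = lb.on_rate(ca)
        rate = kon + lb.k_off_ca
        t = np.arange(300) * 1e-3
        states = propagate(sensor, SensorState.all_apo(),
                           np.full(300, ca), 1e-3)
        bound = np.array([s.occupancy[1, :].sum() for s in states])
        expected = kon / rate * (1.0 - np.exp(-rate * t))
        assert np.abs(bound - expected).max() < 1e-6


class TestClassification:
    def test_all_apo(self):
        out = classify_states(SensorState.all_apo())[0]
        assert (out.fast_fluorescent, out.slow_fluorescent,
                out.slow_nonfluorescent, out.nonfluorescent_other) \
            == (0.0, 0.0, 0.0, 1.0)

    def test_n_lobe_pathway_is_fast_fluorescent(self):
        P = np.zeros((3, 3))
        P[2, 0] = 1.0
        out = classify_states(SensorState(P))[0]
        assert out.fast_fluorescent == 1.0

    def test_partition_along_trajectory(self, toy_sensor, rng):
        ca = np.abs(rng.uniform(0, 3, 500))
        states = propagate(toy_sensor, SensorState.all_apo(), ca, 1e-3)
        for out in classify_states(states):
            total = (out.fast_fluorescent + out.slow_fluorescent
                     + out.slow_nonfluorescent + out.nonfluorescent_other)
            assert total == pytest.approx(1.0, abs=1e-9)


class TestSerialization:
    def test_round_trip(self, toy_sensor, tmp_path):
        path = tmp_path / "sensor.json"
        toy_sensor.save(path)
        back = SensorModel.load(path)
        assert back.lobe_N == toy_sensor.lobe_N
        assert back.lobe_C == toy_sensor.lobe_C
        assert back.R_f == toy_sensor.R_f


@settings(max_examples=30, deadline=None)
@given(ca=st.floats(min_value=0.0, max_value=100.0),
       seed=st.integers(0, 2 ** 16))
def test_steady_state_is_generator_null_vector(ca, seed):
    rng = np.random.default_rng(seed)
    lb_n = lobe(k_off_ca=float(rng.uniform(10, 2000)),
                K_a=float(rng.uniform(0.05, 5)))
    lb_c = lobe(k_off_ca=float(rng.uniform(1, 200)),
                K_a=float(rng.uniform(0.1, 10)))
    sensor = SensorModel(lobe_N=lb_n, lobe_C=lb_c, R_f=5.0)
    pi = steady_state(sensor, ca).vector
    resid = build_generator(sensor, ca) @ pi
    scale = max(lb_n.k_off_ca, lb_c.k_off_ca, lb_n.on_rate(ca))
    assert np.abs(resid).max() < 1e-9 * scale
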