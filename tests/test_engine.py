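"""Simulation engine: training, testing, statistics, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from gfnet import (GazeTrajectory, LearningRuleSpec, Model,
                   ModelConfig, ProtocolConfig, Responses, Seeds,
                   epoch_statistics, run_testing, run_training,
                   sweep_sigmoid_rate)
from gfnet.analysis import window_indices
from gfnet.recipes import make_fixture


def _trained_weights(cfg, epochs):
    m = Model.from_config(cfg)
    run_training(m, epochs=epochs)
    return m.synapses.weights.copy()


class TestTraining:
    def test_zero_epochs_is_noop(self, fixture_config):
        m = Model.from_config(fixture_config)
        w0 = m.synapses.weights.copy()
        run_training(m, epochs=0)
        np.testing.assert_array_equal(m.synapses.weights, w0)

    def test_zero_learning_rate_leaves_weights_unchanged(self, fixture_config):
        cfg = dataclasses.replace(
            fixture_config, learning=LearningRuleSpec("standard_trace",
                                                      learning_rate=0.0))
        m = Model.from_config(cfg)
        w0 = m.synapses.weights.copy()
        run_training(m, epochs=1)
        np.testing.assert_allclose(m.synapses.weights, w0, atol=1e-15)

    def test_training_is_deterministic(self, fixture_config):
        w1 = _trained_weights(fixture_config, 1)
        w2 = _trained_weights(fixture_config, 1)
        np.testing.assert_array_equal(w1, w2)

    def test_weights_stay_unit_norm_and_finite(self, fixture_config):
        m = Model.from_config(fixture_config)
        run_training(m, epochs=1)
        np.testing.assert_allclose(m.synapses.row_norms(), 1.0, atol=1e-9)
        assert np.isfinite(m.synapses.weights).all()

    def test_halving_dt_changes_weights_first_order(self, fixture_config):
        proto = dataclasses.replace(fixture_config.protocol,
                                    training_locations=(0.0,),
                                    fixations_per_location=3)

        def end_weights(dt):
            dyn = dataclasses.replace(fixture_config.dynamics, dt=dt)
            cfg = dataclasses.replace(fixture_config, protocol=proto, dynamics=dyn)
            return _trained_weights(cfg, 1)

        w10, w5, w25 = end_weights(10.0), end_weights(5.0), end_weights(2.5)
        d1 = np.abs(w10 - w5).max()
        d2 = np.abs(w5 - w25).max()
        assert d2 < d1  # differences shrink with the step
        assert d2 / d1 == pytest.approx(0.5, abs=0.25)  # ~first order


class TestKernelParity:
    def test_fused_training_step_matches_reference_path(self, fixture_config):
        # dual route: the fused numba kernel vs the plain numpy
        # weight_derivative / apply_update / drive composition
        import gfnet.learning as L
        from gfnet.dynamics import (firing_rates, init_state,
                                    percentile_threshold, step_activation,
                                    step_trace)

        cfg = fixture_config
        m = Model.from_config(cfg)
        traj = m.epoch_trajectory(0)

        ref = Model.from_config(cfg)
        p = cfg.dynamics
        state = init_state(cfg.n_output, p)
        n_steps = 200
        for s in range(n_steps):
            e, target = traj.sample(s * p.dt)
            v_in = ref.population.rates(target - e, e)
            d = L.weight_derivative(ref.rule, state.q, state.v, None, None,
                                    v_in, ref.synapses)
            drive = np.sum(ref.synapses.weights *
                           v_in[ref.synapses.pre_index], axis=1)
            L.apply_update(ref.synapses, d, p.dt)
            h_new = step_activation(state.h, drive, p.tau_h, p.dt)
            p_pi = percentile_threshold(h_new, p.pi_pct)
            v_new = firing_rates(h_new, p_pi, p.phi, p.theta)
            state.q = step_trace(state.q, state.v, p.tau_q, p.dt)
            state.h, state.v = h_new, v_new

        sub = GazeTrajectory(
            times=traj.times.copy(), eye=traj.eye.copy(),
            target_h=traj.target_h.copy(), labels=traj.labels.copy())
        # integrate the same number of steps through the engine
        short = dataclasses.replace(cfg)
        m._train_along(_truncate(sub, n_steps * p.dt))
        np.testing.assert_allclose(m.synapses.weights, ref.synapses.weights,
                                   atol=1e-12)
        np.testing.assert_allclose(m.state.h, state.h, atol=1e-12)
        np.testing.assert_allclose(m.state.q, state.q, atol=1e-12)


def _truncate(traj, t_end):
    """Clip a trajectory to [0, t_end] for step-count control in tests."""
    keep = traj.times <= t_end
    n = int(keep.sum())
    import numpy as _np
    times = _np.append(traj.times[:n], t_end)
    k = min(n - 1, len(traj.times) - 2)
    eye_end, _ = traj.sample(t_end)
    return GazeTrajectory(times=times, eye=_np.append(traj.eye[:n], eye_end),
                          target_h=traj.target_h[:n].copy(),
                          labels=traj.labels[:n].copy())


class TestTesting:
    def test_response_shape_and_range_under_standard_protocol(self, fixture_config):
        cfg = dataclasses.replace(fixture_config, protocol=ProtocolConfig())
        m = Model.from_config(cfg)
        r = run_testing(m)
        assert r.values.shape == (cfg.n_output, 4, 80)
        assert r.values.min() >= 0.0 and r.values.max() <= 1.0
        np.testing.assert_allclose(r.eye_positions, [-18.0, -6.0, 6.0, 18.0])
        assert r.target_locations[0] == -79.0 and r.target_locations[-1] == 79.0

    def test_zero_weights_give_constant_responses(self, fixture_config):
        m = Model.from_config(fixture_config)
        m.synapses.weights[:] = 0.0
        r = run_testing(m)
        assert np.ptp(r.values) == pytest.approx(0.0, abs=1e-12)

    def test_testing_is_side_effect_free(self, fixture_config):
        m = Model.from_config(fixture_config)
        h0 = m.state.h.copy()
        w0 = m.synapses.weights.copy()
        r1 = run_testing(m)
        r2 = run_testing(m)
        np.testing.assert_array_equal(r1.values, r2.values)
        np.testing.assert_array_equal(m.state.h, h0)
        np.testing.assert_array_equal(m.synapses.weights, w0)


class TestStatistics:
    def _synthetic_responses(self):
        # five hand-constructed neurons on the standard 4 x 80 grid
        E, T = 4, 80
        eyes = np.array([-18.0, -6.0, 6.0, 18.0])
        targets = np.linspace(-79.0, 79.0, T)
        mats = []
        t = targets[None, :]
        e = eyes[:, None]
        mats.append(np.exp(-((t - 10.0) ** 2) / 200.0) * np.ones((E, 1)))  # head
        mats.append(np.exp(-((t - e - 5.0) ** 2) / 200.0))  # eye-centred
        mats.append(np.full((E, T), 0.2))  # silent -> excluded
        mats.append(np.exp(-((t + 30.0) ** 2) / 400.0) * np.ones((E, 1)))  # head
        mats.append(np.exp(-((t - e + 40.0) ** 2) / 300.0))  # eye-centred
        return Responses(values=np.stack(mats), eye_positions=eyes,
                         target_locations=targets)

    def test_epoch_statistics_match_hand_classification(self):
        resp = self._synthetic_responses()
        st = epoch_statistics(resp)
        # independent oracle: classify each matrix with direct Pearson sums
        w = window_indices(80, 4, 12.0, 2.0)
        labels, pis = [], []
        for n in range(5):
            R = resp.values[n]
            subs = [R[i, w.first[i]:w.first[i] + w.V] for i in range(4)]
            if all(s.max() - s.min() < 0.01 for s in subs):
                labels.append("excluded")
                continue
            pi = np.mean([sps.pearsonr(R[i], R[j]).statistic
                          for i in range(4) for j in range(i + 1, 4)])
            om = np.mean([sps.pearsonr(subs[i], subs[j]).statistic
                          for i in range(4) for j in range(i + 1, 4)])
            labels.append("head_centred" if (pi > 0 and pi > om)
                          else "eye_centred" if (om > 0 and om > pi)
                          else "unclassified")
            if labels[-1] == "head_centred":
                pis.append(pi)
        n_head = labels.count("head_centred")
        assert n_head == 2
        assert st.head_centred_rate == pytest.approx(n_head / 5)
        assert st.mean_head_centredness == pytest.approx(np.mean(pis))

    def test_no_head_centred_neurons_gives_undefined_mean(self):
        resp = self._synthetic_responses()
        resp = Responses(values=resp.values[[1, 4]],
                         eye_positions=resp.eye_positions,
                         target_locations=resp.target_locations)
        st = epoch_statistics(resp)
        assert st.head_centred_rate == 0.0
        assert np.isnan(st.mean_head_centredness)


class TestDirectionalSelfOrganisation:
    def test_peaked_trace_training_raises_head_centred_rate(self):
        # reduced-scale replication of the core effect: training a
        # peaked-gain model with the standard trace rule increases the
        # fraction of head-centred output neurons (seed-averaged).  The
        # effect needs preference grids at least as fine as half the tuning
        # width, so the grid is 2 deg rather than fixture-coarse.
        from gfnet import PopulationConfig
        before, after = [], []
        for s in range(2):
            cfg = ModelConfig(
                population=PopulationConfig(gain_form="peaked",
                                            retinal_step=2.0, eye_step=2.0),
                n_output=100, epochs=10, seeds=Seeds().shifted(s))
            m = Model.from_config(cfg)
            before.append(epoch_statistics(run_testing(m)).head_centred_rate)
            run_training(m)
            after.append(epoch_statistics(run_testing(m)).head_centred_rate)
        assert np.mean(after) > np.mean(before)


class TestSweep:
    def test_sweep_bookkeeping_and_p0_matches_peaked(self, fixture_config):
        cfg = dataclasses.replace(fixture_config, epochs=1)
        table = sweep_sigmoid_rate(cfg, [0.0, 0.5])
        assert len(table) == 4  # one row per (p, phase)
        assert set(table["phase"]) == {"untrained", "trained"}
        # p = 0 mixture equals the pure-peaked model with the same seeds
        peaked = Model.from_config(dataclasses.replace(
            cfg, population=dataclasses.replace(cfg.population,
                                                gain_form="peaked")))
        st = epoch_statistics(run_testing(peaked))
        row = table[(table["p"] == 0.0) & (table["phase"] == "untrained")].iloc[0]
        assert row["head_centred_rate"] == pytest.approx(st.head_centred_rate)

    def test_sweep_rejects_bad_rates(self, fixture_config):
        with pytest.raises(ValueError):
            sweep_sigmoid_rate(fixture_config, [1.2])
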