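"""Covariance maps, prewiring and weight-map export."""

import numpy as np
import pytest

from gfnet import (InputNeuronSpec, PrewiringSpec, covariance_map,
                   export_weight_map, input_mean_response, prewire)
from gfnet.learning import sample_connectivity, init_weights


def _brute_force_cov(a, b, r_grid, e_grid):
    Ra = np.array([[a.response(r, e) for e in e_grid] for r in r_grid])
    Rb = np.array([[b.response(r, e) for e in e_grid] for r in r_grid])
    return np.mean(Ra * Rb) - Ra.mean() * Rb.mean()


class TestCovariance:
    def test_mean_response_matches_double_loop(self, small_peaked_pop):
        r_grid = np.arange(-40.0, 41.0, 8.0)
        e_grid = np.arange(-18.0, 19.0, 6.0)
        for j in (0, 17, 53):
            n = small_peaked_pop.spec(j)
            loop = np.mean([[n.response(r, e) for e in e_grid] for r in r_grid])
            assert input_mean_response(n, r_grid, e_grid) == pytest.approx(loop)
        silent = InputNeuronSpec(alpha=1e4, beta=0.0, gain_form="peaked",
                                 sigma=6.0, rho=6.0)
        assert input_mean_response(silent, r_grid, e_grid) == pytest.approx(0.0)

    def test_covariance_matches_brute_force_on_coarse_grid(self, small_sigmoid_pop):
        pop = small_sigmoid_pop
        r_grid = np.arange(-40.0, 41.0, 8.0)
        e_grid = np.arange(-18.0, 19.0, 6.0)
        ref = pop.spec(40)
        cmap = covariance_map(ref, pop, r_grid, e_grid)
        for j in (0, 13, 40, 101):
            n = pop.spec(j)
            expected = _brute_force_cov(ref, n, r_grid, e_grid)
            ai = int(np.argmin(np.abs(cmap.alpha_grid - n.alpha)))
            bi = int(np.argmin(np.abs(cmap.beta_grid - n.beta)))
            plane = 0 if n.kappa > 0 else 1
            assert cmap.values[ai, bi, plane] == pytest.approx(expected, abs=1e-12)

    def test_self_entry_is_variance_and_symmetry(self, small_peaked_pop):
        pop = small_peaked_pop
        r_grid = np.arange(-40.0, 41.0, 4.0)
        e_grid = np.arange(-18.0, 19.0, 6.0)
        a, b = pop.spec(30), pop.spec(31)
        ca = covariance_map(a, pop, r_grid, e_grid)
        cb = covariance_map(b, pop, r_grid, e_grid)
        ai = int(np.argmin(np.abs(ca.alpha_grid - a.alpha)))
        bi = int(np.argmin(np.abs(ca.beta_grid - a.beta)))
        var = _brute_force_cov(a, a, r_grid, e_grid)
        assert var > 0
        assert ca.values[ai, bi] == pytest.approx(var, abs=1e-12)
        # cov(a, b) == cov(b, a)
        aj = int(np.argmin(np.abs(cb.alpha_grid - a.alpha)))
        bj = int(np.argmin(np.abs(cb.beta_grid - a.beta)))
        ai2 = int(np.argmin(np.abs(ca.alpha_grid - b.alpha)))
        bi2 = int(np.argmin(np.abs(ca.beta_grid - b.beta)))
        assert ca.values[ai2, bi2] == pytest.approx(cb.values[aj, bj], abs=1e-12)

    def test_peaked_map_localised_at_reference(self, small_peaked_pop):
        pop = small_peaked_pop
        ref = InputNeuronSpec(alpha=0.0, beta=0.0, gain_form="peaked",
                              sigma=6.0, rho=6.0)
        cmap = covariance_map(ref, pop)
        ai, bi = np.unravel_index(np.nanargmax(cmap.values), cmap.values.shape)
        assert cmap.alpha_grid[ai] == pytest.approx(0.0)
        assert cmap.beta_grid[bi] == pytest.approx(0.0)

    def test_sigmoid_map_elongated_along_eye_preference(self, small_sigmoid_pop):
        # half-max extent of the positive-gain half-map should be wider in
        # beta* than in alpha* for a sigmoid reference neuron
        pop = small_sigmoid_pop
        ref = InputNeuronSpec(alpha=0.0, beta=0.0, gain_form="sigmoid",
                              sigma=6.0, kappa=0.0625)
        cmap = covariance_map(ref, pop)
        plus = cmap.values[:, :, 0]
        ai, bi = np.unravel_index(np.nanargmax(plus), plus.shape)
        half = plus[ai, bi] / 2.0
        alpha_extent = np.ptp(cmap.alpha_grid[np.any(plus > half, axis=1)])
        beta_extent = np.ptp(cmap.beta_grid[np.any(plus > half, axis=0)])
        assert beta_extent > alpha_extent


class TestPrewiring:
    @pytest.mark.parametrize("alpha,kappa_sign,elevated", [
        (15.0, 1, True),   # h - beta <= alpha <= h + W/2 with h = beta = 0
        (40.0, 1, False),  # beyond h + W/2 = 30
        (-15.0, -1, True),  # h - W/2 <= alpha <= h - beta
        (-40.0, -1, False),
        (5.0, -1, False),  # above h - beta = 0 for negative gain
    ])
    def test_membership_against_direct_interval_check(self, alpha, kappa_sign,
                                                      elevated):
        spec = PrewiringSpec()
        h, beta, W = 0.0, 0.0, spec.W
        if kappa_sign > 0:
            inside = (h - beta <= alpha) and (alpha <= h + W / 2)
        else:
            inside = (h - W / 2 <= alpha) and (alpha <= h - beta)
        assert inside == elevated

    def test_prewired_weights_structure(self, small_sigmoid_pop):
        pop = small_sigmoid_pop
        spec = PrewiringSpec(assigned_locations=(-20.0, 0.0, 20.0))
        syn, assigned = prewire(pop, N=12, spec=spec, phi=0.5, seed=2)
        # balanced assignment
        vals, counts = np.unique(assigned, return_counts=True)
        assert set(vals) == {-20.0, 0.0, 20.0} and np.all(counts == 4)
        np.testing.assert_allclose(syn.row_norms(), 1.0, atol=1e-12)
        # every weight is (a scaled) elevated or depressed value
        for i in range(12):
            pre = syn.pre_index[i]
            a, b, k = pop.alpha[pre], pop.beta[pre], pop.kappa[pre]
            hloc = assigned[i]
            pos = (hloc - b <= a) & (a <= hloc + spec.W / 2)
            neg = (hloc - spec.W / 2 <= a) & (a <= hloc - b)
            want = np.where(np.where(k > 0, pos, neg), spec.elevated, spec.depressed)
            np.testing.assert_allclose(syn.weights[i],
                                       want / np.linalg.norm(want), atol=1e-12)

    def test_prewire_rejects_non_sigmoid_population(self, small_peaked_pop):
        with pytest.raises(ValueError):
            prewire(small_peaked_pop, N=5, phi=0.5, seed=0)


class TestHebbianCovariancePrediction:
    def test_hebbian_trained_weights_correlate_with_covariance_maps(self):
        # competitive Hebbian learning converges towards the input
        # covariance structure: a trained neuron's weight vector should
        # correlate positively (cell-wise) with the covariance map of its
        # strongest afferent
        import dataclasses
        from scipy import stats
        from gfnet import Model
        from gfnet.learning import LearningRuleSpec
        from gfnet.recipes import make_fixture, pattern_trajectory

        cfg = make_fixture(seed=0)
        cfg = dataclasses.replace(
            cfg,
            dynamics=dataclasses.replace(cfg.dynamics, tau_h=30.0, dt=3.0),
            learning=LearningRuleSpec("hebbian"))
        m = Model.from_config(cfg)
        m._train_along(pattern_trajectory(n_patterns=200,
                                          retinal_range=(-40.0, 40.0), seed=5))
        r_grid = np.arange(-40.0, 41.0, 4.0)
        e_grid = np.arange(-18.0, 19.0, 4.0)
        rs = []
        for i in np.argsort(-m.synapses.weights.max(axis=1))[:5]:
            pre = m.synapses.pre_index[i]
            w = m.synapses.weights[i]
            jstar = int(pre[int(np.argmax(w))])
            cm = covariance_map(m.population.spec(jstar), m.population,
                                r_grid, e_grid)
            ai = np.rint((m.population.alpha[pre] - cm.alpha_grid[0]) / 4.0).astype(int)
            bi = np.rint((m.population.beta[pre] - cm.beta_grid[0]) / 4.0).astype(int)
            rs.append(stats.pearsonr(w, cm.values[ai, bi]).statistic)
        assert np.mean(rs) > 0.0


class TestWeightMap:
    def test_round_trip_and_sentinel(self, small_peaked_pop):
        pop = small_peaked_pop
        syn = init_weights(sample_connectivity(3, pop.size, 0.2, seed=5), seed=6)
        m = export_weight_map(syn.weights[0], syn.pre_index[0], pop)
        assert m.shape == (pop.retinal_grid.size, pop.eye_grid.size)
        for k in range(syn.n_afferents):
            j = syn.pre_index[0, k]
            ai = int(np.argmin(np.abs(pop.retinal_grid - pop.alpha[j])))
            bi = int(np.argmin(np.abs(pop.eye_grid - pop.beta[j])))
            assert m[ai, bi] == syn.weights[0, k]
        assert np.isnan(m).sum() == m.size - len(set(syn.pre_index[0].tolist()))

    def test_gain_split_for_sigmoid_population(self, small_sigmoid_pop):
        pop = small_sigmoid_pop
        syn = init_weights(sample_connectivity(2, pop.size, 0.3, seed=7), seed=8)
        m = export_weight_map(syn.weights[0], syn.pre_index[0], pop)
        assert m.ndim == 3 and m.shape[2] == 2
        k = 0
        j = syn.pre_index[0, k]
        plane = 0 if pop.kappa[j] > 0 else 1
        ai = int(np.argmin(np.abs(pop.retinal_grid - pop.alpha[j])))
        bi = int(np.argmin(np.abs(pop.eye_grid - pop.beta[j])))
        assert m[ai, bi, plane] == syn.weights[0, k]
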