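"""Contrastive estimator, parameter updates and the training loop."""

import numpy as np
import pytest

from eqprop import (
    HARD_SIGMOID,
    LOGISTIC,
    ParticleStore,
    RelaxationConfig,
    TrainConfig,
    apply_update,
    eqprop_gradient,
    fit,
    free_phase,
    init_state,
    make_clusters,
    nudged_phase,
    train_minibatch,
)
from eqprop.energy import GradientEstimate, NetworkParams
from eqprop.learning import evaluate, init_network
from eqprop.oracles import ORACLE_RELAXATION, implicit_param_gradient, objective

from conftest import random_interior_state


class TestEqpropGradient:
    def test_identical_states_give_zero(self, small_net):
        p, w = small_net
        u = random_interior_state(p, w, seed=0)
        g = eqprop_gradient(p, w, 0.5, u, u, LOGISTIC)
        assert np.all(g.dW == 0.0) and np.all(g.db == 0.0)

    def test_beta_zero_rejected(self, small_net):
        p, w = small_net
        u = random_interior_state(p, w, seed=0)
        with pytest.raises(ValueError, match="beta"):
            eqprop_gradient(p, w, 0.0, u, u, LOGISTIC)

    def test_two_sided_average_matches_exact_gradient(self, small_net,
                                                      oracle_cfg):
        p, w = small_net
        u_free, _ = free_phase(p, w, init_state(w.x, 6, 3), LOGISTIC,
                               oracle_cfg)
        beta = 1e-3
        up, _ = nudged_phase(p, w, beta, u_free, LOGISTIC, oracle_cfg)
        um, _ = nudged_phase(p, w, -beta, u_free, LOGISTIC, oracle_cfg)
        ep = eqprop_gradient(p, w, beta, u_free, up, LOGISTIC)
        em = eqprop_gradient(p, w, -beta, u_free, um, LOGISTIC)
        two_sided = 0.5 * (ep.flatten(p.mask) + em.flatten(p.mask))
        oracle = implicit_param_gradient(p, w, LOGISTIC, oracle_cfg,
                                         u_free=u_free)
        target = -oracle.flatten(p.mask)
        err = np.linalg.norm(two_sided - target) / np.linalg.norm(target)
        assert err < 1e-2

    def test_both_algebraic_forms_agree(self, small_net, oracle_cfg):
        p, w = small_net
        u_free, _ = free_phase(p, w, init_state(w.x, 6, 3), LOGISTIC,
                               oracle_cfg)
        u_n, _ = nudged_phase(p, w, 0.01, u_free, LOGISTIC, oracle_cfg)
        g1 = eqprop_gradient(p, w, 0.01, u_free, u_n, LOGISTIC,
                             form="total_energy")
        g2 = eqprop_gradient(p, w, 0.01, u_free, u_n, LOGISTIC,
                             form="free_cost")
        np.testing.assert_allclose(g1.dW, g2.dW, atol=1e-10)
        np.testing.assert_allclose(g1.db, g2.db, atol=1e-10)

    def test_single_update_descends_objective(self, small_net, oracle_cfg):
        p, w = small_net
        u_free, _ = free_phase(p, w, init_state(w.x, 6, 3), LOGISTIC,
                               oracle_cfg)
        u_n, _ = nudged_phase(p, w, 0.01, u_free, LOGISTIC, oracle_cfg)
        g = eqprop_gradient(p, w, 0.01, u_free, u_n, LOGISTIC)
        j_before = objective(p, w, LOGISTIC, oracle_cfg)
        p2 = apply_update(p, g, rates=0.05)
        j_after = objective(p2, w, LOGISTIC, oracle_cfg)
        assert j_after <= j_before + 1e-12


class TestApplyUpdate:
    def test_zero_gradient_leaves_parameters_unchanged(self, small_net):
        p, _ = small_net
        g = GradientEstimate(np.zeros_like(p.weights),
                             np.zeros_like(p.biases))
        p2 = apply_update(p, g, rates=(0.1, 0.05))
        np.testing.assert_array_equal(p2.weights, p.weights)
        np.testing.assert_array_equal(p2.biases, p.biases)

    def test_per_layer_rates_scale_blocks(self, small_net):
        p, w = small_net
        u = random_interior_state(p, w, seed=1)
        g = eqprop_gradient(p, w, 1.0, u, random_interior_state(p, w, seed=2),
                            LOGISTIC)
        p2 = apply_update(p, g, rates=(0.1, 0.05))
        sl = p.layer_slices()
        upper = np.triu(g.dW, k=1)
        sym = upper + upper.T
        np.testing.assert_allclose(
            p2.weights[sl[0], sl[1]] - p.weights[sl[0], sl[1]],
            0.1 * sym[sl[0], sl[1]])
        np.testing.assert_allclose(
            p2.weights[sl[1], sl[2]] - p.weights[sl[1], sl[2]],
            0.05 * sym[sl[1], sl[2]])

    def test_wrong_rate_count_rejected(self, small_net):
        p, _ = small_net
        g = GradientEstimate(np.zeros_like(p.weights),
                             np.zeros_like(p.biases))
        with pytest.raises(ValueError, match="rates"):
            apply_update(p, g, rates=(0.1, 0.05, 0.01))

    def test_symmetry_and_mask_survive_many_random_updates(self, small_net):
        p, _ = small_net
        rng = np.random.default_rng(0)
        for _ in range(100):
            raw = rng.normal(size=p.weights.shape)
            g = GradientEstimate(raw, rng.normal(size=p.biases.size))
            p = apply_update(p, g, rates=(0.1, 0.05))
        assert np.max(np.abs(p.weights - p.weights.T)) == 0.0
        assert np.all(p.weights[~p.mask] == 0.0)

    def test_l2_shrinks_weights(self, small_net):
        p, _ = small_net
        g = GradientEstimate(np.zeros_like(p.weights),
                             np.zeros_like(p.biases))
        p2 = apply_update(p, g, rates=1.0, l2_penalty=0.1)
        np.testing.assert_allclose(p2.weights, 0.9 * p.weights)


def _tiny_cfg(**kw):
    defaults = dict(
        beta_magnitude=1.0, random_beta_sign=False, layer_rates=(0.1, 0.05),
        minibatch_size=4, n_epochs=2, seed=0,
        free_config=RelaxationConfig(epsilon=0.5, n_iter=20),
        nudged_config=RelaxationConfig(epsilon=0.5, n_iter=4))
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestTrainMinibatch:
    def test_repeated_example_equals_batch_of_one(self):
        ds = make_clusters(n_classes=2, n_per_class=10, n_features=4, seed=0,
                           valid_fraction=0.0)
        p = init_network((4, 5, 2), seed=0)
        cfg = _tiny_cfg()
        rng = np.random.default_rng(0)
        x, d = ds.features[:1], ds.one_hot[:1]
        X = np.repeat(x, 4, axis=0)
        D = np.repeat(d, 4, axis=0)
        p_one, _ = train_minibatch(p, x, d, [0], cfg, None,
                                   np.random.default_rng(0))
        p_rep, _ = train_minibatch(p, X, D, [0, 1, 2, 3], cfg, None,
                                   np.random.default_rng(0))
        np.testing.assert_allclose(p_rep.weights, p_one.weights, atol=1e-12)
        np.testing.assert_allclose(p_rep.biases, p_one.biases, atol=1e-12)

    def test_random_sign_expectation_is_two_sided_estimate(self):
        # enumerate both beta signs through the actual minibatch path and
        # average the parameter changes; the mean must equal the update
        # built from the explicit two-sided symmetric estimate
        ds = make_clusters(n_classes=2, n_per_class=5, n_features=4, seed=3,
                           valid_fraction=0.0)
        p = init_network((4, 5, 2), seed=3)
        cfg = _tiny_cfg(random_beta_sign=True, beta_magnitude=0.5)
        x, d = ds.features[:1], ds.one_hot[:1]
        # rngs whose first draw selects each sign once
        rng_plus = next(np.random.default_rng(s) for s in range(100)
                        if np.random.default_rng(s).random() >= 0.5)
        rng_minus = next(np.random.default_rng(s) for s in range(100)
                         if np.random.default_rng(s).random() < 0.5)
        p_plus, m_plus = train_minibatch(p, x, d, [0], cfg, None, rng_plus)
        p_minus, m_minus = train_minibatch(p, x, d, [0], cfg, None, rng_minus)
        assert {m_plus["beta"], m_minus["beta"]} == {0.5, -0.5}
        mean_W = 0.5 * (p_plus.weights + p_minus.weights)
        # explicit two-sided estimate through the same phases
        u0 = init_state(x, 5, 2)
        from eqprop import WorldInput
        wi = WorldInput(x=x, d=d)
        u_free, _ = free_phase(p, wi, u0, cfg.activation, cfg.free_config)
        up, _ = nudged_phase(p, wi, 0.5, u_free, cfg.activation,
                             cfg.nudged_config)
        um, _ = nudged_phase(p, wi, -0.5, u_free, cfg.activation,
                             cfg.nudged_config)
        ep = eqprop_gradient(p, wi, 0.5, u_free, up, cfg.activation)
        em = eqprop_gradient(p, wi, -0.5, u_free, um, cfg.activation)
        g2 = GradientEstimate(0.5 * (ep.dW + em.dW), 0.5 * (ep.db + em.db))
        p_two = apply_update(p, g2, rates=cfg.layer_rates)
        np.testing.assert_allclose(mean_W, p_two.weights, atol=1e-14)

    def test_particles_are_stored_after_free_phase(self):
        ds = make_clusters(n_classes=2, n_per_class=10, n_features=4, seed=0,
                           valid_fraction=0.0)
        p = init_network((4, 5, 2), seed=0)
        store = ParticleStore()
        cfg = _tiny_cfg()
        train_minibatch(p, ds.features[:4], ds.one_hot[:4], [0, 1, 2, 3],
                        cfg, store, np.random.default_rng(0))
        assert len(store) == 4
        vals = store.get_batch([0], 7)
        assert np.all(vals >= 0.0) and np.all(vals <= 1.0)


class TestFit:
    def test_zero_epochs_returns_initialization(self):
        ds = make_clusters(n_classes=2, n_per_class=10, n_features=4, seed=0)
        cfg = _tiny_cfg(n_epochs=0)
        p, history, _ = fit(ds, (4, 5, 2), cfg)
        p0 = init_network((4, 5, 2), seed=cfg.seed)
        np.testing.assert_array_equal(p.weights, p0.weights)
        assert len(history) == 0

    def test_linearly_separable_task_reaches_zero_error(self):
        ds = make_clusters(n_classes=2, n_per_class=60, n_features=6,
                           spread=0.04, seed=1, valid_fraction=0.0)
        cfg = _tiny_cfg(minibatch_size=20, n_epochs=50, seed=1,
                        layer_rates=(0.1, 0.05))
        p, history, _ = fit(ds, (6, 10, 2), cfg)
        assert history["train_error"].min() == 0.0

    def test_same_seed_reproduces_metrics(self):
        ds = make_clusters(n_classes=2, n_per_class=20, n_features=4, seed=0)
        cfg = _tiny_cfg(n_epochs=3, random_beta_sign=True)
        _, h1, _ = fit(ds, (4, 5, 2), cfg)
        _, h2, _ = fit(ds, (4, 5, 2), cfg)
        assert h1.equals(h2)

    def test_benchmark_architectures_constructible(self):
        # the three benchmark nets with their published per-layer rates
        for arch, rates in [((784, 500, 10), (0.1, 0.05)),
                            ((784, 500, 500, 10), (0.4, 0.1, 0.01)),
                            ((784, 500, 500, 500, 10),
                             (0.128, 0.032, 0.008, 0.002))]:
            p = init_network(arch, seed=0)
            assert p.layer_sizes == arch
            cfg = _tiny_cfg(layer_rates=rates)
            g = GradientEstimate(np.zeros_like(p.weights),
                                 np.zeros_like(p.biases))
            apply_update(p, g, rates=cfg.layer_rates)

    def test_empty_layer_rejected(self):
        with pytest.raises(ValueError, match="layer"):
            init_network((4, 0, 2), seed=0)

    def test_default_minibatch_size_is_twenty(self):
        assert TrainConfig().minibatch_size == 20

    def test_evaluate_rejects_empty_dataset(self):
        ds = make_clusters(n_classes=2, n_per_class=10, n_features=4, seed=0,
                           valid_fraction=0.0)
        p = init_network((4, 5, 2), seed=0)
        with pytest.raises(ValueError, match="empty"):
            evaluate(p, ds.subset("valid"), HARD_SIGMOID,
                     RelaxationConfig(epsilon=0.5, n_iter=10))
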