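"""Aggregation algorithms, local training, and the round loop."""

import numpy as np
import pytest

from fedusim.errors import ConfigurationError
from fedusim.federation import (ClientUpdate, FLConfig, RoundState,
                                aggregate_fedavg, fedprox_gradient,
                                local_train, lr_at_round, run_federation,
                                server_update_fedopt)
from fedusim.models import ModelSpec, batch_gradient, init_model, predict_proba
from fedusim.privacy import DPConfig
from fedusim._rng import child_seed

SPEC = ModelSpec("multinomial_logistic", input_dim=2, n_classes=2)


def updates_from(vectors, sizes=None):
    sizes = sizes or [1] * len(vectors)
    return [ClientUpdate(i, np.asarray(v, dtype=float), n)
            for i, (v, n) in enumerate(zip(vectors, sizes))]


def blob_sets(K, n_per_client, rng, sep=2.0):
    """Separable two-class Gaussian-blob data split across K clients."""
    sets = []
    for _ in range(K):
        X0 = rng.normal(-sep, 0.7, (n_per_client // 2, 2))
        X1 = rng.normal(sep, 0.7, (n_per_client // 2, 2))
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], n_per_client // 2)
        sets.append((X, y))
    return sets


class TestAggregation:
    def test_unweighted_mean(self):
        out = aggregate_fedavg(updates_from([(0, 2), (2, 4)]))
        np.testing.assert_array_equal(out, [1.0, 3.0])

    def test_single_client_identity(self):
        out = aggregate_fedavg(updates_from([(5.0, -1.0)]))
        np.testing.assert_array_equal(out, [5.0, -1.0])

    def test_sample_size_weighted_mean(self):
        out = aggregate_fedavg(updates_from([(0, 2), (2, 4)], sizes=[1, 3]),
                               weighted=True)
        np.testing.assert_allclose(out, [1.5, 3.5])

    def test_matches_naive_elementwise_loop(self):
        rng = np.random.default_rng(0)
        vectors = rng.standard_normal((6, 40))
        updates = updates_from(vectors)
        out = aggregate_fedavg(updates)
        naive = np.zeros(40)
        for j in range(40):
            naive[j] = sum(v[j] for v in vectors) / 6
        assert np.abs(out - naive).max() < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            aggregate_fedavg(updates_from([(0, 1), (0, 1, 2)]))

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            aggregate_fedavg([])


class TestFedProx:
    def test_zero_mu_is_identity(self):
        g = np.array([1.0, -2.0])
        np.testing.assert_array_equal(
            fedprox_gradient(g, np.ones(2), np.zeros(2), 0.0), g)

    def test_at_global_model_proximal_term_vanishes(self):
        g = np.array([1.0, -2.0])
        w = np.array([0.3, 0.7])
        np.testing.assert_array_equal(fedprox_gradient(g, w, w, 5.0), g)

    def test_quadratic_proximal_objective_minimizer(self):
        """GD with the proximal gradient on F(w)=0.5(w-a)^2 converges to the
        closed-form minimizer (a + mu*w_t)/(1 + mu)."""
        a, w_global, mu = 3.0, 1.0, 0.7
        target = (a + mu * w_global) / (1 + mu)
        w = np.array([0.0])
        for _ in range(400):
            grad_local = w - a
            w = w - 0.1 * fedprox_gradient(grad_local, w,
                                           np.array([w_global]), mu)
        assert abs(w[0] - target) < 1e-6


class TestFedOpt:
    CFG = FLConfig(server_lr=0.01, beta1=0.9, beta2=0.99)

    def test_fixed_point_when_clients_return_global(self):
        w = np.array([1.0, -1.0])
        state = RoundState.initial(w)
        new = server_update_fedopt(state, updates_from([w, w]), self.CFG)
        np.testing.assert_array_equal(new.weights, w)
        np.testing.assert_array_equal(new.m, 0.0)

    def test_momentum_free_reduction(self):
        cfg = FLConfig(server_lr=0.5, beta1=0.0, beta2=0.0, adam_eps=1e-8)
        w = np.array([0.0, 0.0])
        delta = np.array([0.2, -0.4])
        state = RoundState.initial(w)
        new = server_update_fedopt(state, updates_from([w - delta]), cfg)
        expect = w - 0.5 * delta / (np.abs(delta) + 1e-8)
        np.testing.assert_allclose(new.weights, expect, atol=1e-12)

    def test_matches_independent_adam_recurrence(self):
        """Five scripted pseudo-gradients vs a hand-coded Adam recurrence."""
        rng = np.random.default_rng(3)
        deltas = rng.standard_normal((5, 7))
        cfg = self.CFG
        state = RoundState.initial(np.zeros(7))
        # independent recurrence
        w, m, v = np.zeros(7), np.zeros(7), np.zeros(7)
        for t in range(5):
            d = deltas[t]
            update = updates_from([state.weights - d])
            state = server_update_fedopt(state, update, cfg)
            m = 0.9 * m + 0.1 * d
            v = 0.99 * v + 0.01 * d * d
            w = w - 0.01 * m / (np.sqrt(v) + cfg.adam_eps)
            assert np.abs(state.weights - w).max() < 1e-12


class TestLocalTraining:
    def _client(self, n=32, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 2))
        y = (X[:, 0] > 0).astype(int)
        return X, y

    def test_single_step_unrolls_to_one_gradient_update(self):
        X, y = self._client(n=16)
        cfg = FLConfig(rounds=1, local_epochs=1, batch_size=16, client_lr=0.3,
                       mu=0.0, seed=0)
        w0 = init_model(SPEC)
        upd = local_train(w0, X, y, SPEC, cfg, None, round_r=1, seed=5)
        perm = np.random.default_rng(5).permutation(16)
        g, _ = batch_gradient(SPEC, w0, X[perm], y[perm])
        np.testing.assert_allclose(upd.weights, w0 - 0.3 * g, atol=1e-14)

    def test_zero_mu_fedprox_identical_to_fedavg(self):
        X, y = self._client()
        w0 = init_model(SPEC) + 0.1
        a = local_train(w0, X, y, SPEC,
                        FLConfig(algorithm="fedavg", local_epochs=2,
                                 batch_size=8, client_lr=0.1),
                        None, 1, seed=9)
        b = local_train(w0, X, y, SPEC,
                        FLConfig(algorithm="fedprox", mu=0.0, local_epochs=2,
                                 batch_size=8, client_lr=0.1),
                        None, 1, seed=9)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_huge_mu_pins_client_to_global_model(self):
        X, y = self._client()
        w0 = np.full(SPEC.n_params, 0.5)
        cfg = FLConfig(algorithm="fedprox", mu=1e6, local_epochs=1,
                       batch_size=8, client_lr=1e-7)
        upd = local_train(w0, X, y, SPEC, cfg, None, 1, seed=0)
        assert np.linalg.norm(upd.weights - w0) < 1e-4

    def test_learning_rate_decay_schedule(self):
        cfg = FLConfig(client_lr=1e-3)
        assert lr_at_round(cfg, 49) == pytest.approx(1e-3)
        assert lr_at_round(cfg, 51) == pytest.approx(1e-4)
        assert lr_at_round(cfg, 81) == pytest.approx(1e-5)

    def test_step_size_shrinks_by_decay_factor_across_threshold(self):
        X, y = self._client(n=16)
        cfg = FLConfig(local_epochs=1, batch_size=16, client_lr=1e-2)
        w0 = init_model(SPEC)
        d49 = local_train(w0, X, y, SPEC, cfg, None, 49, seed=3).weights - w0
        d51 = local_train(w0, X, y, SPEC, cfg, None, 51, seed=3).weights - w0
        np.testing.assert_allclose(d51, 0.1 * d49, rtol=1e-12)

    def test_client_smaller_than_batch_needs_flag(self):
        X, y = self._client(n=8)
        cfg = FLConfig(batch_size=16)
        with pytest.raises(ConfigurationError, match="batch"):
            local_train(init_model(SPEC), X, y, SPEC, cfg, None, 1, seed=0)
        ok = FLConfig(batch_size=16, allow_small_client=True, local_epochs=1)
        upd = local_train(init_model(SPEC), X, y, SPEC, ok, None, 1, seed=0)
        assert upd.weights.shape == (SPEC.n_params,)

    def test_local_adam_differs_from_sgd_but_shares_stream(self):
        X, y = self._client()
        w0 = init_model(SPEC)
        sgd = local_train(w0, X, y, SPEC, FLConfig(local_epochs=1, batch_size=8,
                                                   client_lr=0.01),
                          None, 1, seed=1)
        adam = local_train(w0, X, y, SPEC,
                           FLConfig(local_epochs=1, batch_size=8,
                                    client_lr=0.01, local_optimizer="adam"),
                           None, 1, seed=1)
        assert not np.allclose(sgd.weights, adam.weights)


class TestRoundLoop:
    def test_single_client_equals_centralized_descent(self):
        rng = np.random.default_rng(0)
        (Xy,) = blob_sets(1, 64, rng)
        cfg = FLConfig(rounds=5, local_epochs=1, batch_size=16,
                       client_lr=0.1, seed=11)
        result = run_federation([Xy], None, SPEC, cfg)
        # manual centralized loop with the same derived seeds
        w = init_model(SPEC)
        for r in range(1, 6):
            w = local_train(w, Xy[0], Xy[1], SPEC, cfg, None, r,
                            child_seed(11, "local", 0, r)).weights
        np.testing.assert_array_equal(result.weights, w)

    def test_fedprox_zero_mu_equals_fedavg_full_run(self):
        rng = np.random.default_rng(1)
        sets = blob_sets(3, 32, rng)
        base = dict(rounds=4, local_epochs=1, batch_size=16, client_lr=0.1,
                    seed=2)
        a = run_federation(sets, None, SPEC, FLConfig(algorithm="fedavg", **base))
        b = run_federation(sets, None, SPEC,
                           FLConfig(algorithm="fedprox", mu=0.0, **base))
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_dp_off_limit_matches_plain_run_end_to_end(self):
        rng = np.random.default_rng(2)
        sets = blob_sets(2, 32, rng)
        cfg = FLConfig(rounds=3, local_epochs=1, batch_size=16, client_lr=0.1,
                       seed=5)
        plain = run_federation(sets, None, SPEC, cfg)
        dp_off = run_federation(sets, None, SPEC, cfg,
                                DPConfig(enabled=True, C=1e9, eta=0.0))
        assert np.abs(plain.weights - dp_off.weights).max() < 1e-12

    def test_separable_task_reaches_high_accuracy(self):
        rng = np.random.default_rng(7)
        sets = blob_sets(4, 64, rng)
        Xt = np.vstack([s[0] for s in blob_sets(1, 200, rng)])
        yt = np.repeat([0, 1], 100)
        cfg = FLConfig(rounds=30, local_epochs=1, batch_size=16,
                       client_lr=0.2, seed=0)
        result = run_federation(sets, (Xt, yt), SPEC, cfg)
        assert result.log.iloc[-1]["test_accuracy"] >= 0.95

    @pytest.mark.parametrize("algorithm", ["fedavg", "fedprox", "fedopt"])
    def test_log_schema_and_determinism(self, algorithm):
        rng = np.random.default_rng(3)
        sets = blob_sets(2, 32, rng)
        cfg = FLConfig(rounds=3, local_epochs=1, batch_size=16,
                       algorithm=algorithm, client_lr=0.1, seed=8)
        a = run_federation(sets, (sets[0][0], sets[0][1]), SPEC, cfg)
        b = run_federation(sets, (sets[0][0], sets[0][1]), SPEC, cfg)
        assert list(a.log["round"]) == [1, 2, 3]
        assert {"train_loss", "test_accuracy", "macro_f1"} <= set(a.log.columns)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_dp_run_logs_privacy_budget(self):
        rng = np.random.default_rng(4)
        sets = blob_sets(2, 32, rng)
        cfg = FLConfig(rounds=2, local_epochs=1, batch_size=16, client_lr=0.05,
                       seed=1)
        result = run_federation(sets, None, SPEC, cfg,
                                DPConfig(enabled=True, C=1.5, eta=2.0))
        log = result.log
        assert (log["eps_basic"] > 0).all()
        assert (log["eps_sublinear"] <= log["eps_basic"]).all()
        assert log["eps_basic"].is_monotonic_increasing
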