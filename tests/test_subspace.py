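"""Spike-triggered statistics, STC/iSTAC subspaces, and MNE models."""

import numpy as np
import pytest

from rfctx.info import score_distribution, single_spike_info
from rfctx.subspace import (
    FilterBank,
    QNModel,
    SpikeTriggeredStats,
    istac_fit,
    istac_gradient,
    istac_objective,
    lowrank_scores,
    lowrank_select,
    mne_fit,
    mne_scores,
    null_filters,
    refine_filters,
    spike_triggered_stats,
    stc_filters,
)

LOG2 = np.log(2.0)


class TestSpikeTriggeredStats:
    def test_single_spike_gives_that_sample(self, rng):
        X = rng.standard_normal((10, 4))
        y = np.zeros(10, int)
        y[3] = 1
        st = spike_triggered_stats(X, y)
        np.testing.assert_allclose(st.sta, X[3])
        np.testing.assert_allclose(st.stc, 0.0, atol=1e-12)

    def test_uniform_counts_give_ensemble_mean(self, rng):
        X = rng.standard_normal((50, 3))
        st = spike_triggered_stats(X, np.full(50, 2))
        np.testing.assert_allclose(st.sta, X.mean(axis=0), atol=1e-12)

    def test_matches_replication_oracle(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.integers(0, 3, 30)
        y[0] = 1  # ensure at least one spike
        st = spike_triggered_stats(X, y)
        rep = np.repeat(X, y, axis=0)
        np.testing.assert_allclose(st.sta, rep.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(st.stc,
                                   np.cov(rep.T, bias=True), atol=1e-12)

    def test_zero_spikes_rejected(self, rng):
        with pytest.raises(ValueError, match="zero spikes"):
            spike_triggered_stats(rng.standard_normal((5, 2)), np.zeros(5))


class TestSTCFilters:
    def test_isotropic_case_has_null_eigenvalues_at_variance(self, rng):
        X = rng.standard_normal((20000, 5))
        y = rng.poisson(0.5, 20000)
        st = spike_triggered_stats(X, y)
        nulls = null_filters(st, 2)
        np.testing.assert_allclose(nulls.eigenvalues, 1.0, atol=0.06)

    def test_planted_variance_excess_recovered(self, rng):
        d, n = 6, 40000
        X = rng.standard_normal((n, d))
        w = np.zeros(d)
        w[2] = 1.0
        rate = 0.2 * (1 + (X @ w) ** 2)
        y = rng.poisson(rate)
        st = spike_triggered_stats(X, y)
        bank = stc_filters(st, 1)
        assert abs(bank.filters[:, 0] @ w) > 0.99
        assert bank.filters.T @ bank.filters == pytest.approx(1.0, abs=1e-8)

    def test_suppressive_direction_also_ranks_first(self, rng):
        d, n = 5, 40000
        X = rng.standard_normal((n, d))
        w = np.eye(d)[1]
        rate = 0.4 * np.exp(-1.5 * (X @ w) ** 2)
        y = rng.poisson(rate)
        st = spike_triggered_stats(X, y)
        bank = stc_filters(st, 1)
        assert abs(bank.filters[:, 0] @ w) > 0.99
        assert bank.eigenvalues[0] < 1.0  # variance-shrunk direction

    def test_too_many_filters_rejected(self, rng):
        st = spike_triggered_stats(rng.standard_normal((50, 3)),
                                   np.ones(50))
        with pytest.raises(ValueError):
            stc_filters(st, 4)


def gaussian_kl_bits(mean, cov):
    """Oracle: KL(N(mean, cov) || N(0, I)) in bits."""
    k = len(mean)
    return 0.5 * (np.trace(cov) + mean @ mean - k
                  - np.linalg.slogdet(cov)[1]) / LOG2


class TestISTAC:
    def make_stats(self, rng, d=6):
        A = rng.standard_normal((d, d))
        lam = A @ A.T / d + 0.5 * np.eye(d)
        mu = 0.4 * rng.standard_normal(d)
        return SpikeTriggeredStats(mu, lam, 100.0, np.ones(d))

    def test_white_spike_ensemble_carries_zero_information(self, rng):
        st = SpikeTriggeredStats(np.zeros(4), np.eye(4), 10.0, np.ones(4))
        B = np.linalg.qr(rng.standard_normal((4, 2)))[0]
        assert istac_objective(B, st) == pytest.approx(0.0, abs=1e-12)

    def test_objective_equals_gaussian_kl_oracle(self, rng):
        st = self.make_stats(rng)
        for m in (1, 2, 3):
            B = np.linalg.qr(rng.standard_normal((6, m)))[0]
            kl = gaussian_kl_bits(B.T @ st.sta, B.T @ st.stc @ B)
            assert istac_objective(B, st) == pytest.approx(kl, abs=1e-10)

    def test_gradient_matches_central_differences(self, rng):
        st = self.make_stats(rng)
        B = np.linalg.qr(rng.standard_normal((6, 2)))[0]
        G = istac_gradient(B, st)
        eps = 1e-6
        for i in range(6):
            for j in range(2):
                Bp, Bm = B.copy(), B.copy()
                Bp[i, j] += eps
                Bm[i, j] -= eps
                fd = (istac_objective(Bp, st)
                      - istac_objective(Bm, st)) / (2 * eps)
                assert G[i, j] == pytest.approx(fd, abs=1e-5)

    def test_full_space_objective_is_basis_invariant(self, rng):
        st = self.make_stats(rng, d=4)
        vals = [istac_objective(np.linalg.qr(rng.standard_normal((4, 4)))[0],
                                st) for _ in range(3)]
        np.testing.assert_allclose(vals, vals[0], atol=1e-8)

    def test_mean_shift_direction_recovered(self):
        d = 8
        mu = np.zeros(d)
        mu[3] = 1.5
        st = SpikeTriggeredStats(mu, np.eye(d), 100.0, np.ones(d))
        bank = istac_fit(st, 1)
        assert abs(bank.filters[:, 0] @ mu / np.linalg.norm(mu)) > 0.99

    def test_marginal_information_non_increasing(self, rng):
        st = self.make_stats(rng)
        bank = istac_fit(st, 3)
        assert bank.marginal_info is not None
        assert np.all(np.diff(bank.marginal_info) <= 1e-6)


class TestMNE:
    def test_stimulus_independent_spiking_recovers_base_rate(self, rng):
        n, d, p = 20000, 4, 0.2
        X = rng.standard_normal((n, d))
        y = (rng.random(n) < p).astype(int)
        m = mne_fit(X, y, C=1.0)
        assert np.linalg.norm(m.v) < 0.05
        assert np.linalg.norm(m.J) < 0.05
        assert m.c == pytest.approx(np.log(p / (1 - p)), abs=0.1)

    def test_generative_parameter_recovery(self):
        rng = np.random.default_rng(7)
        n, d = 30000, 5
        X = rng.standard_normal((n, d))
        c, v = -2.0, np.zeros(d)
        v[0] = 0.8
        J = np.zeros((d, d))
        J[1, 1], J[2, 2], J[1, 2] = 0.6, -0.5, 0.2
        J[2, 1] = J[1, 2]
        z = c + X @ v + np.einsum("ij,ij->i", X @ J, X)
        y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(int)
        m = mne_fit(X, y, C=1.0)
        assert np.linalg.norm(m.v - v) / np.linalg.norm(v) < 0.10
        assert np.linalg.norm(m.J - J) / np.linalg.norm(J) < 0.10
        np.testing.assert_array_equal(m.J, m.J.T)

    def test_loss_gradient_matches_central_differences(self, rng):
        from rfctx.subspace import _mne_loss_grad

        n, d = 40, 3
        X = rng.standard_normal((n, d))
        y = rng.integers(0, 3, n).astype(float)
        ytil = np.where(y == 0, -1.0, 1.0)
        beta = np.maximum(y, 1.0)
        theta = 0.1 * rng.standard_normal(1 + d + d * d)
        _, g = _mne_loss_grad(theta, X, y, ytil, beta, 0.7, d)
        eps = 1e-6
        for j in range(len(theta)):
            e = np.zeros_like(theta)
            e[j] = eps
            lp, _ = _mne_loss_grad(theta + e, X, y, ytil, beta, 0.7, d)
            lm, _ = _mne_loss_grad(theta - e, X, y, ytil, beta, 0.7, d)
            assert g[j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)


class TestLowRank:
    def test_zero_quadratic_part_returns_normalized_v(self, rng):
        d = 4
        v = rng.standard_normal(d)
        model = QNModel(0.0, v, np.zeros((d, d)))
        X = rng.standard_normal((200, d))
        y = rng.poisson(0.5, 200)
        out = lowrank_select(model, 1, X, y)
        assert len(out.selected) == 1
        f = out.selected[0]
        assert f.source == "v"
        np.testing.assert_allclose(f.w, v / np.linalg.norm(v), atol=1e-12)
        np.testing.assert_allclose(lowrank_scores(out, X), X @ v, atol=1e-10)

    def test_planted_rank_two_recovered(self, rng):
        d = 6
        w1, w2 = np.eye(d)[0], np.eye(d)[3]
        J = 1.5 * np.outer(w1, w1) - 0.8 * np.outer(w2, w2)
        model = QNModel(0.0, np.zeros(d), J)
        X = rng.standard_normal((500, d))
        y = rng.poisson(0.5, 500)
        out = lowrank_select(model, 2, X, y)
        got = sorted(abs(f.w @ w1) + abs(f.w @ w2) for f in out.selected
                     if f.source == "J")
        assert all(g > 0.99 for g in got)

    def test_selection_invariant_to_eigenvector_sign(self, rng):
        d = 5
        J = np.diag([2.0, -1.0, 0.1, 0.0, 0.0])
        X = rng.standard_normal((300, d))
        y = rng.poisson(0.4, 300)
        m1 = lowrank_select(QNModel(0.0, np.zeros(d), J.copy()), 2, X, y)
        z1 = lowrank_scores(m1, X)
        m2 = lowrank_select(QNModel(0.0, np.zeros(d), J.copy()), 2, X, y)
        for f in m2.selected:
            f.w = -f.w
        z2 = lowrank_scores(m2, X)
        np.testing.assert_allclose(z1, z2, atol=1e-10)  # quadratic terms

    def test_four_filter_configuration(self, rng):
        d = 8
        J = np.diag([3.0, -2.0, 1.5, -1.0, 0.1, 0, 0, 0])
        v = 0.5 * np.eye(d)[7]
        X = rng.standard_normal((400, d))
        y = rng.poisson(0.4, 400)
        out = lowrank_select(QNModel(0.0, v, J), 4, X, y)
        assert len(out.selected) == 4

    def test_refinement_gradients_match_central_differences(self, rng):
        from rfctx.subspace import _lowrank_loss_grad

        d, n = 4, 30
        X = rng.standard_normal((n, d))
        y = rng.integers(0, 2, n).astype(float)
        ytil = np.where(y == 0, -1.0, 1.0)
        beta = np.maximum(y, 1.0)
        meta = [("v", 1.0), ("J", 0.8), ("J", -0.5)]
        theta = rng.standard_normal(3 * d)
        _, g = _lowrank_loss_grad(theta, meta, X, y, ytil, beta, 0.6, -1.0, d)
        eps = 1e-6
        for j in range(len(theta)):
            e = np.zeros_like(theta)
            e[j] = eps
            lp, _ = _lowrank_loss_grad(theta + e, meta, X, y, ytil, beta,
                                       0.6, -1.0, d)
            lm, _ = _lowrank_loss_grad(theta - e, meta, X, y, ytil, beta,
                                       0.6, -1.0, d)
            assert g[j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)

    def test_refinement_never_hurts_validation_information(self, rng):
        d, n = 5, 6000
        X = rng.standard_normal((n, d))
        w = np.eye(d)[0]
        z = 1.2 * (X @ w) ** 2 - 1.5
        y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(int)
        m = mne_fit(X[: n // 2], y[: n // 2], C=1.0)
        m = lowrank_select(m, 2, X[: n // 2], y[: n // 2])
        Xv, yv = X[n // 2 :], y[n // 2 :]

        def val_info(model):
            zz = lowrank_scores(model, Xv)
            return single_spike_info(score_distribution(zz, yv, 15))

        before = val_info(m)
        refined = refine_filters(m, X[: n // 2], y[: n // 2],
                                 [0.1, 1.0], Xv, yv)
        assert val_info(refined) >= before - 1e-9
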