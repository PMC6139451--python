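"""Context-model scores, convex subproblems, and the alternating fitter."""

import numpy as np
import pytest

from rfctx.context import (
    ContextField,
    ContextModelParams,
    SolverConfig,
    alternating_fit,
    cf_design_rows,
    data_loss,
    default_params,
    fit_double_cf_intensity,
    flip_and_restart,
    linear_constant,
    make_regularizer,
    rf_design_rows,
    similarity_scores,
    solve_glm_subproblem,
    solve_linear_subproblem,
)
from rfctx.simulate import generate_context_poisson, make_bar_stimulus
from rfctx.stimulus import (
    ContextWindowSpec,
    StimulusEnsemble,
    apply_basis,
    build_lagged_design,
    extract_context_vector,
)


def random_context_model(rng, n_bars, n_lags, window):
    cf = ContextField(rng.standard_normal((window.height, window.width)), window)
    return ContextModelParams(rng.standard_normal(),
                              rng.standard_normal((n_bars, n_lags)), [cf])


def brute_force_scores(params, design):
    """Oracle: nested-sum evaluation of the similarity score."""
    ens = design.ensemble
    L = design.n_lags
    out = np.zeros(design.n_samples)
    for i in range(design.n_samples):
        s = params.w0
        for b in range(ens.n_bars):
            for lag in range(L):
                x = ens.frames[b, i + lag]
                acc = 0.0
                for cf in params.cfs:
                    if not cf.mask_for(params.rf.size)[b * L + lag]:
                        continue
                    patch = extract_context_vector(ens, i, b, lag, cf.spec, L)
                    patch = patch.copy()
                    patch[cf.spec.origin] = 0.0
                    acc += np.sum(cf.weights * patch)
                s += params.rf[b, lag] * x * (1.0 + acc)
        out[i] = s
    return out


class TestSimilarityScores:
    def test_matches_nested_sum_oracle(self, toy_design, small_window, rng):
        params = random_context_model(rng, 5, 4, small_window)
        np.testing.assert_allclose(similarity_scores(params, toy_design),
                                   brute_force_scores(params, toy_design),
                                   atol=1e-12)

    def test_zero_cf_reduces_to_linear_score(self, toy_design, small_window):
        params = default_params(toy_design, 1, small_window)
        g = np.random.default_rng(0)
        params.rf = g.standard_normal(params.rf.shape)
        params.w0 = 0.7
        z = similarity_scores(params, toy_design)
        np.testing.assert_allclose(z, 0.7 + toy_design.X @ params.rf_flat,
                                   atol=1e-12)

    def test_zero_rf_gives_constant_bias(self, toy_design, small_window, rng):
        params = random_context_model(rng, 5, 4, small_window)
        params.rf[:] = 0.0
        np.testing.assert_allclose(similarity_scores(params, toy_design),
                                   params.w0)

    def test_both_score_representations_agree(self, toy_design, small_window, rng):
        """The RF-linear and CF-linear forms of z are the same function."""
        for seed in range(3):
            params = random_context_model(np.random.default_rng(seed), 5, 4,
                                          small_window)
            z_rf = params.w0 + rf_design_rows(params, toy_design) @ params.rf_flat
            z_cf = linear_constant(params, toy_design) + cf_design_rows(
                params, toy_design, 0) @ params.cfs[0].weights.ravel()
            np.testing.assert_allclose(z_rf, z_cf, atol=1e-10)


class TestDesignRows:
    def test_rf_rows_equal_raw_design_without_cfs(self, toy_design):
        params = default_params(toy_design, 1)
        np.testing.assert_array_equal(rf_design_rows(params, toy_design),
                                      toy_design.X)

    @pytest.mark.parametrize("which", ["rf", "cf"])
    def test_rows_match_central_differences(self, toy_design, small_window,
                                            rng, which):
        params = random_context_model(rng, 5, 4, small_window)
        A = (rf_design_rows if which == "rf" else
             lambda p, d: cf_design_rows(p, d, 0))(params, toy_design)
        eps = 1e-6
        idx = [0, 3, 7] if which == "rf" else [1, 3, 5]
        for j in idx:
            plus, minus = params.copy(), params.copy()
            tgt_p = plus.rf.ravel() if which == "rf" else plus.cfs[0].weights.ravel()
            tgt_m = minus.rf.ravel() if which == "rf" else minus.cfs[0].weights.ravel()
            tgt_p[j] += eps
            tgt_m[j] -= eps
            fd = (similarity_scores(plus, toy_design)
                  - similarity_scores(minus, toy_design)) / (2 * eps)
            np.testing.assert_allclose(A[:, j], fd, atol=1e-6)

    def test_single_cf_weight_scales_assigned_column(self):
        frames = np.ones((3, 8), np.int8)
        ens = StimulusEnsemble(frames)
        d = build_lagged_design(ens, 3)
        win = ContextWindowSpec(1, 3, (0, 1))
        params = default_params(d, 1, win)
        params.rf[:] = 1.0
        params.cfs[0].weights[0, 0] = 0.5
        A = rf_design_rows(params, d)
        # interior elements see one context neighbour of value 1 at weight .5
        manual = brute_force_scores(params, d)
        np.testing.assert_allclose(params.w0 + A @ params.rf_flat, manual,
                                   atol=1e-12)

    def test_empty_assignment_rejected(self, toy_design, small_window):
        params = default_params(toy_design, 1, small_window)
        params.cfs[0].rf_assignment = np.zeros(params.rf.size, bool)
        with pytest.raises(ValueError, match="empty"):
            cf_design_rows(params, toy_design, 0)


class TestSubproblemSolvers:
    def test_identity_system_returns_targets(self):
        y = np.arange(5.0)
        w = solve_linear_subproblem(np.eye(5), y, np.zeros(5), 1.0, None)
        np.testing.assert_allclose(w, y, atol=1e-12)

    def test_strong_regularization_shrinks_to_zero(self, rng):
        A = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        w = solve_linear_subproblem(A, y, np.zeros(30), 1e-9, np.eye(4))
        assert np.linalg.norm(w) < 1e-5

    def test_matches_ridge_oracle(self, rng):
        A = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        C, G = 0.37, np.eye(5)
        w = solve_linear_subproblem(A, y, np.zeros(20), C, G)
        oracle = np.linalg.solve(A.T @ A + G / (2 * C), A.T @ y)
        np.testing.assert_allclose(w, oracle, atol=1e-8)

    def test_singular_unregularized_system_falls_back_to_pseudoinverse(self):
        A = np.zeros((6, 3))
        A[:, 0] = 1.0  # rank-deficient design
        y = np.ones(6)
        with pytest.warns(UserWarning, match="pseudoinverse"):
            w = solve_linear_subproblem(A, y, np.zeros(6), 1.0, None)
        np.testing.assert_allclose(A @ w, y, atol=1e-10)  # min-norm solution

    def test_logistic_balanced_intercept_is_zero(self):
        w = solve_glm_subproblem(np.ones((10, 1)), np.array([1, 0] * 5), None,
                                 1.0, None, "logistic")
        np.testing.assert_allclose(w, [0.0], atol=1e-6)

    def test_poisson_intercept_is_log_mean(self, rng):
        y = rng.poisson(3.0, 200)
        w = solve_glm_subproblem(np.ones((200, 1)), y, None, 1.0, None,
                                 "poisson")
        np.testing.assert_allclose(w, [np.log(y.mean())], atol=1e-6)

    @pytest.mark.parametrize("family", ["logistic", "poisson"])
    def test_glm_solution_is_stationary(self, rng, family):
        """The solver lands where central differences of the loss vanish."""
        A = rng.standard_normal((60, 3))
        y = rng.poisson(1.0, 60).astype(float)
        k = 0.2 * rng.standard_normal(60)
        C, G = 0.5, 0.3 * np.eye(3)
        w = solve_glm_subproblem(A, y, k, C, G, family, tol=1e-8)

        def loss(wv):
            z = k + A @ wv
            return C * data_loss(family, z, y) + 0.5 * wv @ (G.T @ G) @ wv

        eps = 1e-5
        for j in range(3):
            e = np.zeros(3)
            e[j] = eps
            fd = (loss(w + e) - loss(w - e)) / (2 * eps)
            assert abs(fd) < 1e-4


class TestRegularizers:
    def test_l2_is_identity(self):
        np.testing.assert_array_equal(make_regularizer("l2", (2, 3)), np.eye(6))

    def test_laplacian_annihilates_constant_field(self):
        G = make_regularizer("laplacian", (4, 5))
        np.testing.assert_allclose(G @ np.ones(20), 0.0, atol=1e-12)

    def test_laplacian_matches_hand_built_stencil(self):
        G = make_regularizer("laplacian", (3, 3))
        # explicit 5-point stencil with one-sided boundaries on a 3x3 grid
        def idx(r, c):
            return 3 * r + c
        H = np.zeros((9, 9))
        for r in range(3):
            for c in range(3):
                i = idx(r, c)
                for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < 3 and 0 <= cc < 3:
                        H[i, i] += 1.0
                        H[i, idx(rr, cc)] -= 1.0
        np.testing.assert_allclose(G, H, atol=1e-12)


def planted_context_data(n_frames=8000, seed=3):
    nb, L = 8, 8
    raw = make_bar_stimulus(nb, n_frames, seed=seed)
    enc = StimulusEnsemble(apply_basis(raw.frames, "bright"), frame_rate=60.0)
    spec = ContextWindowSpec(5, 5)
    cf = np.zeros((5, 5))
    cf[2, 4], cf[2, 0], cf[1, 3] = 0.8, -0.5, 0.4
    cf[spec.origin] = 0.0
    rf = np.zeros((nb, L))
    rf[3:6, 5:] = 0.35
    rf[2, 4] = 0.2
    params = ContextModelParams(-1.8, rf, [ContextField(cf.copy(), spec)])
    ens = generate_context_poisson(params, np.exp, enc, seed=seed + 1)
    return build_lagged_design(ens, L), params, spec


def cosine(a, b):
    a, b = np.ravel(a), np.ravel(b)
    return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))


@pytest.fixture(scope="module")
def recovery():
    design, truth, spec = planted_context_data()
    cfg = SolverConfig(family="poisson", seed=0, final_cv=False)
    res = alternating_fit(design, design.counts,
                          default_params(design, 1, spec), cfg)
    res = flip_and_restart(res, design, design.counts, cfg)
    return design, truth, spec, cfg, res


class TestAlternatingFit:
    def test_recovers_planted_fields(self, recovery):
        _, truth, _, _, res = recovery
        s = np.sign(cosine(res.params.rf, truth.rf))
        assert s * cosine(res.params.rf, truth.rf) > 0.9
        assert s * cosine(res.params.cfs[0].weights,
                          truth.cfs[0].weights) > 0.9

    def test_loss_trace_monotone(self, recovery):
        *_, res = recovery
        assert np.all(np.diff(res.loss_trace) <= 1e-8)

    def test_cf_origin_stays_zero(self, recovery):
        *_, res = recovery
        assert res.params.cfs[0].weights[res.params.cfs[0].spec.origin] == 0.0

    def test_pure_ln_data_leaves_cfs_small(self):
        """On data from a CF-free Poisson model the fitted CF stays minor."""
        nb, L = 6, 6
        raw = make_bar_stimulus(nb, 8000, seed=11)
        enc = StimulusEnsemble(apply_basis(raw.frames, "bright"),
                               frame_rate=60.0)
        rf = np.zeros((nb, L))
        rf[2:4, 3:] = 0.5
        truth = ContextModelParams(-1.5, rf, [])
        from rfctx.simulate import generate_context_poisson as gen
        ens = gen(truth, np.exp, enc, seed=12)
        design = build_lagged_design(ens, L)
        spec = ContextWindowSpec(5, 5)
        cfg = SolverConfig(family="poisson", seed=0, final_cv=False)
        res = alternating_fit(design, design.counts,
                              default_params(design, 1, spec), cfg)
        rf_scale = np.linalg.norm(res.params.rf)
        assert np.linalg.norm(res.params.cfs[0].weights) <= 0.05 * rf_scale * 5

    def test_reduces_to_plain_glm_with_no_cfs(self, toy_design):
        cfg = SolverConfig(family="poisson", C=0.5, final_cv=False)
        res = alternating_fit(toy_design, toy_design.counts,
                              default_params(toy_design, 0), cfg)
        A1 = np.hstack([toy_design.X, np.ones((toy_design.n_samples, 1))])
        G = np.zeros((A1.shape[1], A1.shape[1]))
        G[:-1, :-1] = np.eye(A1.shape[1] - 1)
        w = solve_glm_subproblem(A1, toy_design.counts, None, 0.5, G,
                                 "poisson", tol=1e-8)
        np.testing.assert_allclose(np.append(res.params.rf_flat,
                                             res.params.w0), w, atol=1e-4)


class TestFlipAndRestart:
    def test_positive_rf_left_unchanged(self, recovery_fixture=None):
        design, truth, spec = planted_context_data(4000, seed=5)
        cfg = SolverConfig(family="poisson", final_cv=False)
        res = alternating_fit(design, design.counts,
                              default_params(design, 1, spec), cfg)
        if abs(res.params.rf.min()) <= res.params.rf.max():
            out = flip_and_restart(res, design, design.counts, cfg)
            assert out is res and not out.flipped

    def test_negated_solution_is_flipped_back(self):
        design, truth, spec = planted_context_data(4000, seed=6)
        cfg = SolverConfig(family="poisson", final_cv=False)
        res = alternating_fit(design, design.counts,
                              default_params(design, 1, spec), cfg)
        res.params.rf = -res.params.rf
        for cf in res.params.cfs:
            cf.weights = -cf.weights
        loss_before = res.loss_trace[-1]
        out = flip_and_restart(res, design, design.counts, cfg)
        assert out.flipped
        assert out.params.rf.max() >= abs(out.params.rf.min())
        assert out.loss_trace[-1] <= loss_before + 1e-6 * abs(loss_before)


class TestDoubleCFIntensity:
    def test_requires_intensity_design(self, toy_design):
        cfg = SolverConfig(family="linear", final_cv=False)
        with pytest.raises(ValueError, match="bright\\+dark"):
            fit_double_cf_intensity(toy_design, toy_design.counts, cfg)

    def test_two_cf_fit_not_worse_than_shared(self):
        g = np.random.default_rng(21)
        raw = (g.integers(0, 2, (6, 4000)) * 2 - 1).astype(np.int8)
        stacked = apply_basis(raw, "bright+dark")
        counts = g.poisson(0.5, 4000)
        ens = StimulusEnsemble(stacked, counts, n_planes=2)
        design = build_lagged_design(ens, 5)
        win = ContextWindowSpec(3, 3)
        cfg = SolverConfig(family="linear", final_cv=False, max_outer=20)
        two = fit_double_cf_intensity(design, design.counts, cfg, win)
        assert len(two.params.cfs) == 2
        masks = [cf.mask_for(two.params.rf.size) for cf in two.params.cfs]
        assert not np.any(masks[0] & masks[1])
        assert np.all(masks[0] | masks[1])

    def test_parameter_count_matches_four_filter_ln(self):
        """Space-time-intensity RF (2*256) + two CFs ~ four 256-dim filters."""
        rf_params = 2 * 16 * 16
        cf_params = 2 * (9 * 9 - 1)
        ln4 = 4 * 16 * 16
        assert rf_params + cf_params == 672
        assert ln4 == 1024  # same order; equality holds for full-RF CFs
        full_cf = 2 * (16 * 16 - 1)
        assert rf_params + full_cf == ln4 - 2
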