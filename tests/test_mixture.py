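import itertools

import numpy as np
import pytest
from scipy import optimize, stats

from aftmix import synthetic
from aftmix.mixture import (
    DegenerateComponentError,
    MixtureAFTModel,
    PenaltyConfig,
    active_genes,
    censored_moments,
    classify,
    component_loglik,
    e_step,
    fit_em,
    m_step,
    mixture_loglik,
    scad,
    scad_deriv,
    select_order,
    tune_lambdas,
)
from aftmix.survival_data import SurvivalDataset
from tests.conftest import two_component_config


def _model(pi, beta0, beta, sigma, genes=None):
    beta = np.atleast_2d(beta)
    return MixtureAFTModel(K=len(np.atleast_1d(pi)), pi=np.atleast_1d(pi),
                           beta0=np.atleast_1d(beta0), beta=beta,
                           sigma=np.atleast_1d(sigma), gene_names=genes or [])


def _dataset(X, y, delta):
    n, p = X.shape
    return SurvivalDataset(X=X, y=y, delta=np.asarray(delta, dtype=int),
                           gene_names=[f"g{j}" for j in range(p)],
                           sample_ids=[f"s{i}" for i in range(n)])


class TestComponentLoglik:
    def test_event_at_mean_is_standard_normal_density(self):
        assert component_loglik(0.0, 1, 0.0, 1.0) == pytest.approx(
            -0.9189385332046727)

    def test_censored_at_median_is_log_half(self):
        assert component_loglik(0.0, 0, 0.0, 1.0) == pytest.approx(np.log(0.5))

    def test_deep_tail_finite(self):
        v = component_loglik(10.0, 0, 0.0, 1.0)
        assert np.isfinite(v)
        assert v == pytest.approx(-53.23, abs=0.01)

    def test_matches_high_precision_tail_oracle(self):
        """Censored term vs 50-digit erfc evaluation across z in [-10, 10]."""
        import sympy

        for z in [-10.0, -5.0, -1.0, 0.0, 1.0, 3.0, 5.0, 8.0, 10.0]:
            oracle = float(sympy.log(sympy.erfc(sympy.Float(z, 50) /
                                                sympy.sqrt(2)) / 2).evalf(50))
            assert component_loglik(z, 0, 0.0, 1.0) == pytest.approx(
                oracle, abs=1e-8)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            component_loglik(0.0, 1, 0.0, 0.0)


class TestMixtureLoglik:
    def test_single_component_collapses_to_sum(self, censored_dataset):
        m = _model([1.0], [1.0], [[1.0, -0.5, 0.0]], [0.6])
        direct = float(np.sum(component_loglik(
            censored_dataset.y, censored_dataset.delta,
            1.0 + censored_dataset.X @ np.array([1.0, -0.5, 0.0]), 0.6)))
        assert mixture_loglik(censored_dataset, m) == pytest.approx(direct)

    def test_duplicated_component_invariance(self, censored_dataset):
        one = _model([1.0], [1.0], [[1.0, -0.5, 0.0]], [0.6])
        two = _model([0.5, 0.5], [1.0, 1.0],
                     [[1.0, -0.5, 0.0], [1.0, -0.5, 0.0]], [0.6, 0.6])
        assert mixture_loglik(censored_dataset, two) == pytest.approx(
            mixture_loglik(censored_dataset, one), rel=1e-12)

    def test_two_point_case_against_direct_summation(self):
        X = np.array([[0.5], [-1.0]])
        y = np.array([0.3, 1.2])
        delta = [1, 0]
        m = _model([0.3, 0.7], [0.0, 1.0], [[1.0], [-0.5]], [0.8, 1.5])
        ds = _dataset(X, y, delta)
        total = 0.0
        for i in range(2):
            acc = 0.0
            for k in range(2):
                mu = m.beta0[k] + X[i, 0] * m.beta[k, 0]
                if delta[i] == 1:
                    fk = stats.norm.pdf(y[i], mu, m.sigma[k])
                else:
                    fk = stats.norm.sf(y[i], mu, m.sigma[k])
                acc += m.pi[k] * fk
            total += np.log(acc)
        assert mixture_loglik(ds, m) == pytest.approx(total, abs=1e-12)


class TestScad:
    def test_zero(self):
        assert scad(0.0, 1.0) == 0.0

    def test_linear_branch_boundary(self):
        assert scad(1.0, 1.0, 3.7) == pytest.approx(1.0)

    def test_constant_branch(self):
        assert scad(10.0, 1.0, 3.7) == pytest.approx((3.7 + 1) / 2)

    def test_derivative_is_gradient_of_penalty(self):
        # finite-difference check across all three branches
        for t in [0.3, 1.5, 2.5, 4.0]:
            fd = (scad(t + 1e-6, 1.0) - scad(t - 1e-6, 1.0)) / 2e-6
            assert scad_deriv(t, 1.0) == pytest.approx(fd, abs=1e-5)

    def test_continuity_at_knots(self):
        for lam, a in [(0.5, 3.7), (1.0, 2.5)]:
            assert scad(lam - 1e-12, lam, a) == pytest.approx(
                scad(lam + 1e-12, lam, a), abs=1e-9)
            assert scad(a * lam - 1e-12, lam, a) == pytest.approx(
                scad(a * lam + 1e-12, lam, a), abs=1e-9)


class TestEStep:
    def test_identical_components_return_priors(self, censored_dataset):
        m = _model([0.3, 0.7], [1.0, 1.0],
                   [[1.0, -0.5, 0.0]] * 2, [0.6, 0.6])
        tau = e_step(censored_dataset, m)
        np.testing.assert_allclose(tau, np.tile([0.3, 0.7],
                                                (censored_dataset.n, 1)))

    def test_single_component_all_ones(self, censored_dataset):
        m = _model([1.0], [1.0], [[1.0, -0.5, 0.0]], [0.6])
        np.testing.assert_allclose(e_step(censored_dataset, m), 1.0)

    def test_one_observation_hand_normalization(self):
        ds = _dataset(np.array([[0.2]]), np.array([0.5]), [1])
        m = _model([0.4, 0.6], [0.0, 1.0], [[1.0], [0.3]], [0.7, 1.1])
        num = []
        for k in range(2):
            mu = m.beta0[k] + 0.2 * m.beta[k, 0]
            num.append(m.pi[k] * stats.norm.pdf(0.5, mu, m.sigma[k]))
        expected = np.array(num) / np.sum(num)
        np.testing.assert_allclose(e_step(ds, m)[0], expected, atol=1e-12)

    def test_rows_sum_to_one(self, censored_dataset):
        m = _model([0.5, 0.5], [0.0, 2.0],
                   [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]], [0.5, 1.0])
        tau = e_step(censored_dataset, m)
        np.testing.assert_allclose(tau.sum(axis=1), 1.0, atol=1e-10)


class TestCensoredMoments:
    def test_half_normal_mean(self):
        m1, _ = censored_moments(0.0, 0.0, 1.0)
        assert m1 == pytest.approx(np.sqrt(2 / np.pi))

    def test_half_normal_second_moment(self):
        _, m2 = censored_moments(0.0, 0.0, 1.0)
        assert m2 == pytest.approx(1.0)

    def test_matches_quadrature_oracle(self):
        """Truncated-normal moments vs 30-digit quadrature, incl. a deep tail."""
        import mpmath

        mpmath.mp.dps = 30
        for y, mu, sigma in [(3.0, 0.0, 1.0), (1.0, -0.5, 0.7), (8.0, 0.0, 1.0)]:
            pdf = lambda t: mpmath.npdf(t, mu, sigma)
            tail = mpmath.quad(pdf, [y, mpmath.inf])
            f1 = float(mpmath.quad(lambda t: t * pdf(t), [y, mpmath.inf]) / tail)
            f2 = float(mpmath.quad(lambda t: t * t * pdf(t), [y, mpmath.inf]) / tail)
            m1, m2 = censored_moments(y, mu, sigma)
            assert m1 == pytest.approx(f1, abs=1e-8)
            assert m2 == pytest.approx(f2, abs=1e-8)


class TestMStep:
    def test_ols_fixed_point_unpenalized(self, small_dataset):
        """lambda = 0, K = 1, no censoring: OLS is a fixed point of the M-step."""
        A = np.column_stack([np.ones(small_dataset.n), small_dataset.X])
        coef, *_ = np.linalg.lstsq(A, small_dataset.y, rcond=None)
        resid = small_dataset.y - A @ coef
        start = _model([1.0], [coef[0]], [coef[1:]],
                       [np.sqrt(np.mean(resid**2))],
                       genes=small_dataset.gene_names)
        tau = np.ones((small_dataset.n, 1))
        updated, _ = m_step(small_dataset, tau, PenaltyConfig(lam=[0.0]), start)
        assert updated.beta0[0] == pytest.approx(coef[0], abs=1e-6)
        np.testing.assert_allclose(updated.beta[0], coef[1:], atol=1e-6)

    def test_huge_lambda_zeroes_all_slopes(self, censored_dataset):
        tau = np.ones((censored_dataset.n, 1))
        start = _model([1.0], [0.5], [[0.5, 0.5, 0.5]], [1.0],
                       genes=censored_dataset.gene_names)
        model = start
        for _ in range(60):
            model, _ = m_step(censored_dataset, tau,
                              PenaltyConfig(lam=[1e6]), model)
        np.testing.assert_array_equal(model.beta[0], 0.0)
        # intercept and scale converge to the censored-normal location/scale MLE
        def negll(params):
            mu, log_s = params
            return -np.sum(component_loglik(censored_dataset.y,
                                            censored_dataset.delta, mu,
                                            np.exp(log_s)))
        opt = optimize.minimize(negll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert model.beta0[0] == pytest.approx(opt.x[0], abs=1e-4)
        assert model.sigma[0] == pytest.approx(np.exp(opt.x[1]), abs=1e-4)

    def test_empty_component_flagged_degenerate(self, small_dataset):
        tau = np.zeros((small_dataset.n, 2))
        tau[:, 0] = 1.0
        start = _model([0.5, 0.5], [0.0, 0.0],
                       np.zeros((2, small_dataset.p)), [1.0, 1.0],
                       genes=small_dataset.gene_names)
        with pytest.raises(DegenerateComponentError):
            m_step(small_dataset, tau, PenaltyConfig(lam=[0.0, 0.0]), start)


class TestFitEM:
    def test_k1_unpenalized_matches_closed_form(self, small_dataset):
        fit = fit_em(small_dataset, K=1, penalty=PenaltyConfig(lam=[0.0]),
                     n_starts=1, seed=0)
        A = np.column_stack([np.ones(small_dataset.n), small_dataset.X])
        coef, *_ = np.linalg.lstsq(A, small_dataset.y, rcond=None)
        resid = small_dataset.y - A @ coef
        assert fit.model.beta0[0] == pytest.approx(coef[0], abs=1e-6)
        np.testing.assert_allclose(fit.model.beta[0], coef[1:], atol=1e-6)
        # MLE scale divides by n
        assert fit.model.sigma[0] == pytest.approx(
            np.sqrt(np.mean(resid**2)), abs=1e-6)

    def test_beats_exhaustive_hard_assignment_oracle(self):
        """n=8 toy: EM log-likelihood >= best of all 2^8 hard assignments."""
        rng = np.random.default_rng(42)
        x = np.array([-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0])
        z = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        y = np.where(z == 0, 1.0 + 2.0 * x, -1.0 - 1.0 * x)
        y = y + 0.3 * rng.standard_normal(8)
        ds = _dataset(x[:, None], y, np.ones(8))

        def group_fit(idx):
            if len(idx) < 3:
                return None
            A = np.column_stack([np.ones(len(idx)), x[idx]])
            coef, *_ = np.linalg.lstsq(A, y[idx], rcond=None)
            resid = y[idx] - A @ coef
            s = np.sqrt(np.mean(resid**2))
            return coef, max(s, 1e-3)

        best_oracle = -np.inf
        for assign in itertools.product([0, 1], repeat=8):
            assign = np.array(assign)
            g0, g1 = np.flatnonzero(assign == 0), np.flatnonzero(assign == 1)
            f0, f1 = group_fit(g0), group_fit(g1)
            if f0 is None or f1 is None:
                continue
            m = _model([len(g0) / 8, len(g1) / 8],
                       [f0[0][0], f1[0][0]],
                       [[f0[0][1]], [f1[0][1]]],
                       [f0[1], f1[1]])
            best_oracle = max(best_oracle, mixture_loglik(ds, m))

        fit = fit_em(ds, K=2, penalty=PenaltyConfig(lam=[0.0, 0.0]),
                     n_starts=20, seed=1, min_component_weight=2.0)
        assert fit.loglik >= best_oracle - 1e-6

    def test_penalized_loglik_trace_monotone(self):
        cfg = two_component_config(seed=3)
        ds = synthetic.simulate_dataset(cfg).dataset
        fit = fit_em(ds, 2, PenaltyConfig(lam=[0.1, 0.1]), n_starts=3, seed=3)
        tr = fit.loglik_trace
        assert np.all(np.diff(tr) >= -1e-8 * (np.abs(tr[1:]) + 1.0))

    def test_component_one_is_shorter_survival(self):
        cfg = two_component_config(seed=4)
        ds = synthetic.simulate_dataset(cfg).dataset
        fit = fit_em(ds, 2, PenaltyConfig(lam=[0.15, 0.15]), n_starts=3, seed=4)
        mu = fit.model.linear_predictor(ds.X).mean(axis=0)
        assert mu[0] < mu[1]

    def test_likelihood_invariant_under_start_relabeling(self):
        """Different seeds that find the same optimum report identical loglik."""
        cfg = two_component_config(seed=5)
        ds = synthetic.simulate_dataset(cfg).dataset
        f1 = fit_em(ds, 2, PenaltyConfig(lam=[0.15, 0.15]), n_starts=4, seed=5)
        f2 = fit_em(ds, 2, PenaltyConfig(lam=[0.15, 0.15]), n_starts=4, seed=99)
        assert f1.loglik == pytest.approx(f2.loglik, rel=1e-4)
        assert f1.model.pi[0] == pytest.approx(f2.model.pi[0], abs=0.02)

    def test_huge_lambda_gives_intercept_only_mixture(self):
        cfg = two_component_config(seed=6)
        ds = synthetic.simulate_dataset(cfg).dataset
        fit = fit_em(ds, 2, PenaltyConfig(lam=[50.0, 50.0]), n_starts=3,
                     seed=6, refit_support=False)
        np.testing.assert_array_equal(fit.model.beta, 0.0)

    def test_tau_rows_sum_to_one(self):
        cfg = two_component_config(seed=7)
        ds = synthetic.simulate_dataset(cfg).dataset
        fit = fit_em(ds, 2, PenaltyConfig(lam=[0.2, 0.2]), n_starts=2, seed=7)
        np.testing.assert_allclose(fit.tau.sum(axis=1), 1.0, atol=1e-10)


class TestTuneLambdas:
    def test_zero_grid_returns_zero_with_no_selection(self, small_dataset):
        pen = tune_lambdas(small_dataset, 1, lambda_grid=np.array([0.0]))
        np.testing.assert_array_equal(pen.lam, 0.0)

    def test_duplicate_grid_entries_do_not_change_choice(self):
        cfg = two_component_config(seed=8, n=150, p=6)
        ds = synthetic.simulate_dataset(cfg).dataset
        grid = np.array([0.05, 0.1, 0.2, 0.4])
        a = tune_lambdas(ds, 1, lambda_grid=grid, seed=8, n_starts=2)
        b = tune_lambdas(ds, 1, lambda_grid=np.repeat(grid, 2), seed=8,
                         n_starts=2)
        np.testing.assert_allclose(a.lam, b.lam)

    def test_single_component_recovers_true_support(self):
        """3 true predictors of 20, n=500: chosen penalty keeps all three."""
        hits = 0
        for seed in range(20):
            beta = np.zeros((1, 20))
            beta[0, [2, 9, 15]] = [1.0, -0.8, 0.6]
            cfg = synthetic.SimConfig(
                n=500, p=20, K_true=1, pi=np.array([1.0]),
                beta0=np.array([2.0]), beta=beta, sigma=np.array([0.7]),
                censor_rate=0.3, seed=1000 + seed)
            ds = synthetic.simulate_dataset(cfg).dataset
            pen = tune_lambdas(ds, 1, seed=seed, n_starts=2)
            fit = fit_em(ds, 1, pen, n_starts=2, seed=seed)
            act = active_genes(fit.model, 1)
            if {"g003", "g010", "g016"} <= act:
                hits += 1
        assert hits >= 16


class TestSelectOrder:
    def test_single_option(self, censored_dataset):
        sel = select_order(censored_dataset, K_range=(1,), seed=0, n_starts=2)
        assert sel.best_K == 1

    def test_single_component_data_prefers_k1(self):
        hits = 0
        for seed in range(6):
            beta = np.zeros((1, 8))
            beta[0, :2] = [1.0, -0.7]
            cfg = synthetic.SimConfig(
                n=250, p=8, K_true=1, pi=np.array([1.0]),
                beta0=np.array([2.0]), beta=beta, sigma=np.array([0.8]),
                censor_rate=0.3, seed=2000 + seed)
            ds = synthetic.simulate_dataset(cfg).dataset
            sel = select_order(ds, K_range=(1, 2), seed=seed, n_starts=2)
            if sel.best_K == 1:
                hits += 1
        assert hits >= 5


class TestClassify:
    def test_map_label_and_tie_break(self):
        fit = type("F", (), {})()
        fit.tau = np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]])
        labels, table = classify(fit, sample_ids=["a", "b", "c"],
                                 delta=[1, 0, 1])
        np.testing.assert_array_equal(labels, [1, 1, 2])
        assert list(table.columns) == ["sample_id", "delta", "tau_1", "tau_2",
                                       "map_label"]

    def test_high_accuracy_on_well_separated_data(self):
        """MAP labels recover the truth >= 95% when components barely overlap."""
        cfg = two_component_config(seed=9, n=400, censor_rate=0.15)
        cfg.beta0 = np.array([0.0, 6.0])
        sim = synthetic.simulate_dataset(cfg)
        fit = fit_em(sim.dataset, 2, PenaltyConfig(lam=[0.1, 0.1]),
                     n_starts=4, seed=9)
        labels, _ = classify(fit)
        acc = max(np.mean(labels - 1 == sim.z), np.mean(labels - 1 == 1 - sim.z))
        assert acc >= 0.95


class TestActiveGenes:
    def test_all_zero_empty(self):
        m = _model([1.0], [0.0], np.zeros((1, 4)), [1.0],
                   genes=["a", "b", "c", "d"])
        assert active_genes(m, 1) == set()

    def test_threshold_respected(self):
        m = _model([1.0], [0.0], [[1e-9, 0.5, -2.0, 0.0]], [1.0],
                   genes=["a", "b", "c", "d"])
        assert active_genes(m, 1) == {"b", "c"}

    def test_component_out_of_range(self):
        m = _model([1.0], [0.0], np.zeros((1, 2)), [1.0], genes=["a", "b"])
        with pytest.raises(ValueError):
            active_genes(m, 2)


class TestPublishedCoefficientTable:
    """Counts from the transcribed CRC two-component coefficient estimates."""

    def test_active_counts(self):
        import aftmix

        model = aftmix.crc_coefficient_model()
        assert len(active_genes(model, 1)) == 83
        assert len(active_genes(model, 2)) == 18

    def test_doubly_inactive_count(self):
        import aftmix

        model = aftmix.crc_coefficient_model()
        inactive = (set(model.gene_names) - active_genes(model, 1)
                    - active_genes(model, 2))
        assert len(inactive) == 12
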