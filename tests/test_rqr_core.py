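import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import growthqr as gq
from growthqr.rqr_core import UndefinedCapacityError

from _oracle import (bruteforce_optimum, check_loss_ref, lad_optimum,
                     objective_ref, random_tiny_instance)

RESID_TOL = 1e-7


class TestCheckLoss:
    @pytest.mark.parametrize("u,tau,expected", [
        (1.0, 0.2, 0.2),    # positive branch: tau * u
        (-1.0, 0.2, 0.8),   # negative branch: -(1 - tau) * u
        (0.0, 0.2, 0.0),
        (0.0, 0.8, 0.0),
        (2.5, 0.5, 1.25),
        (-2.0, 0.9, 0.2),
    ])
    def test_branch_values(self, u, tau, expected):
        assert gq.check_loss(u, tau) == pytest.approx(expected)

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.1, 1.5])
    def test_tau_domain(self, tau):
        with pytest.raises(ValueError):
            gq.check_loss(1.0, tau)

    @settings(deadline=None)
    @given(u=st.floats(-1e6, 1e6), tau=st.floats(0.01, 0.99))
    def test_nonnegative_zero_iff_zero(self, u, tau):
        v = gq.check_loss(u, tau)
        assert v >= 0.0
        assert (v == 0.0) == (u == 0.0)


def solve(y, X, tau, lam, **kw):
    return gq.solve_rqr(gq.RQRProblem(y=np.asarray(y, float),
                                      X=np.asarray(X, float), tau=tau, lam=lam, **kw))


class TestSolveRQR:
    def test_intercept_only_median(self):
        fit = solve([1.0, 2.0, 3.0], np.empty((3, 0)), 0.5, 0.0)
        assert fit.mu_hat == pytest.approx(2.0)
        assert fit.beta_hat.size == 0

    def test_huge_penalty_zeroes_all_effects(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, (12, 4)).astype(float)
        y = rng.normal(10, 3, 12)
        for tau in (0.2, 0.5, 0.8):
            fit = solve(y, X, tau, 1e6)
            assert np.all(fit.beta_hat == 0.0)
            # intercept solves the reduced intercept-only quantile problem
            best_const = min(gq.check_loss(y - c, tau).sum() for c in y)
            assert gq.check_loss(y - fit.mu_hat, tau).sum() == pytest.approx(best_const, abs=1e-8)

    def test_matches_bruteforce_on_random_tiny_instances(self):
        """Objective agrees with independent vertex enumeration (40 instances)."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            y, X, tau, lam = random_tiny_instance(rng)
            fit = solve(y, X, tau, lam)
            assert fit.objective == pytest.approx(bruteforce_optimum(y, X, tau, lam), abs=1e-6)

    def test_objective_self_consistent(self):
        rng = np.random.default_rng(3)
        y, X, tau, lam = random_tiny_instance(rng)
        fit = solve(y, X, tau, lam)
        recomputed = objective_ref(y, X, tau, lam, fit.mu_hat, fit.beta_hat)
        assert fit.objective == pytest.approx(recomputed, abs=1e-8)

    def test_quantile_coverage_at_zero_penalty(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            y, X, tau, _ = random_tiny_instance(rng)
            fit = solve(y, X, tau, 0.0)
            r = y - fit.fitted
            n = y.size
            assert np.sum(r < -RESID_TOL) <= n * tau + 1e-9
            assert n * tau <= np.sum(r <= RESID_TOL) + 1e-9

    def test_median_fit_is_least_absolute_deviations(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            y, X, _, _ = random_tiny_instance(rng)
            fit = solve(y, X, 0.5, 0.0)
            assert 2.0 * fit.objective == pytest.approx(lad_optimum(y, X), abs=1e-6)

    def test_agrees_with_statsmodels_quantreg(self):
        """Independent solver cross-check at lam=0 (unpenalized QR)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(15)
        X = rng.integers(0, 3, (40, 3)).astype(float)
        y = 5.0 + X @ np.array([1.0, -0.5, 0.0]) + rng.normal(0, 1, 40)
        for tau in (0.2, 0.5, 0.8):
            fit = solve(y, X, tau, 0.0)
            qr = sm.QuantReg(y, sm.add_constant(X)).fit(q=tau)
            sm_obj = gq.check_loss(y - qr.fittedvalues, tau).sum()
            assert fit.objective <= sm_obj + 1e-6
            assert fit.objective == pytest.approx(sm_obj, rel=1e-4, abs=1e-6)

    def test_perturbation_optimality(self):
        """Objective at the solution beats 1000 random perturbations of it."""
        rng = np.random.default_rng(21)
        y, X, tau, lam = random_tiny_instance(rng)
        fit = solve(y, X, tau, lam)
        p = X.shape[1]
        for scale in (1e-3, 1e-1, 1.0):
            for _ in range(334):
                mu = fit.mu_hat + rng.normal(0, scale)
                beta = fit.beta_hat + rng.normal(0, scale, p)
                assert objective_ref(y, X, tau, lam, mu, beta) >= fit.objective - 1e-9

    def test_shrinkage_path_monotone_small(self):
        rng = np.random.default_rng(33)
        X = rng.integers(0, 3, (60, 10)).astype(float)
        y = 20.0 + X @ rng.normal(0, 2, 10) + rng.normal(0, 1, 60)
        norms = [np.abs(solve(y, X, 0.5, lam).beta_hat).sum()
                 for lam in np.arange(0.0, 10.5, 0.5)]
        assert all(b <= a + 1e-6 for a, b in zip(norms, norms[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            gq.RQRProblem(y=np.empty(0), X=np.empty((0, 2)), tau=0.5, lam=0.0)
        with pytest.raises(ValueError):
            gq.RQRProblem(y=np.ones(3), X=np.ones((3, 1)), tau=1.0, lam=0.0)
        with pytest.raises(ValueError):
            gq.RQRProblem(y=np.ones(3), X=np.ones((3, 1)), tau=0.5, lam=-1.0)


def fit_with(fitted, tau=0.5):
    fitted = np.asarray(fitted, float)
    return gq.RQRFit(tau=tau, lam=0.0, mu_hat=0.0, beta_hat=np.empty(0),
                     objective=0.0, fitted=fitted, pseudo_r1=np.nan, n_nonzero=0)


class TestPredictiveCapacity:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 4.0])
        assert gq.predictive_capacity(fit_with(y), y) == pytest.approx(1.0)

    def test_antitone_fit(self):
        y = np.array([1.0, 2.0, 4.0])
        assert gq.predictive_capacity(fit_with(-y), y) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # y=[1,2,4], fitted=[1,2,3]: r = 9 / (2*sqrt(21))
        y = np.array([1.0, 2.0, 4.0])
        cap = gq.predictive_capacity(fit_with([1.0, 2.0, 3.0]), y)
        assert cap == pytest.approx(0.9819805060619659, abs=1e-12)

    def test_constant_fit_undefined(self):
        with pytest.raises(UndefinedCapacityError):
            gq.predictive_capacity(fit_with([2.0, 2.0, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestSelectLambda:
    def test_singleton_grid(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, (10, 2)).astype(float)
        y = rng.normal(0, 1, 10) + X[:, 0]
        lam, table, fit = gq.select_lambda(y, X, 0.5, [0.5])
        assert lam == 0.5 and len(table) == 1 and fit.lam == 0.5

    def test_tie_goes_to_larger_lambda(self):
        # a vanishing penalty leaves the lam=0 vertex unchanged -> identical capacity
        rng = np.random.default_rng(4)
        X = rng.integers(0, 3, (10, 2)).astype(float)
        y = 1.0 + X[:, 0] + rng.normal(0, 0.5, 10)
        lam, table, _ = gq.select_lambda(y, X, 0.5, [0.0, 1e-9])
        caps = table["capacity"].to_numpy()
        assert caps[0] == pytest.approx(caps[1], abs=1e-9)
        assert lam == 1e-9

    def test_moderate_penalty_can_win(self):
        """Frozen strong-signal instance where lam=0.5 beats lam=0 in capacity."""
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, (10, 3)).astype(float)
        y = 1.0 + X @ np.array([2.0, 0.0, 0.0]) + rng.normal(0, 1, 10)
        grid = [0.0, 0.5, 1.0, 2.0]
        lam, table, _ = gq.select_lambda(y, X, 0.8, grid)
        assert lam > 0.0
        # exhaustive check: the winner maximizes the reported capacities
        caps = table["capacity"].to_numpy()
        best = np.nanmax(caps)
        assert caps[table["lambda"].to_numpy() == lam][0] == pytest.approx(best)

    def test_all_undefined_raises(self):
        y = np.array([1.0, 2.0, 3.0])
        X = np.zeros((3, 1))
        with pytest.raises(UndefinedCapacityError):
            gq.select_lambda(y, X, 0.5, [10.0, 20.0])


class TestPseudoR1:
    def test_perfect_fit_is_one(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        assert gq.pseudo_r1(fit_with(y), y, 0.5) == pytest.approx(1.0)

    def test_quantile_fit_is_zero(self):
        y = np.array([1.0, 2.0, 3.0, 10.0])
        q = np.quantile(y, 0.5, method="inverted_cdf")
        assert gq.pseudo_r1(fit_with(np.full(4, q)), y, 0.5) == pytest.approx(0.0)

    def test_hand_computed_toy(self):
        # y=[1,2,3,10], fitted=[1,2,3,4], tau=0.5: V_full=3, V_null=5 -> 0.4
        y = np.array([1.0, 2.0, 3.0, 10.0])
        assert gq.pseudo_r1(fit_with([1.0, 2.0, 3.0, 4.0]), y, 0.5) == pytest.approx(0.4)

    def test_constant_response_undefined(self):
        y = np.full(4, 2.0)
        with pytest.raises(ValueError):
            gq.pseudo_r1(fit_with(y), y, 0.5)


@pytest.fixture(scope="module")
def instance():
    rng = np.random.default_rng(11)
    n, p = 20, 4
    X = rng.integers(0, 3, (n, p)).astype(float)
    X[:, 3] = 0.0  # structurally null marker: beta stays 0 in every replicate
    y = 5.0 + 8.0 * X[:, 0] + rng.normal(0, 1, n)
    return y, X


class TestBootstrapEffects:
    def test_same_seed_is_bit_identical(self, instance):
        y, X = instance
        a = gq.bootstrap_effects(y, X, 0.5, 0.5, reps=20, seed=9)
        b = gq.bootstrap_effects(y, X, 0.5, 0.5, reps=20, seed=9)
        np.testing.assert_array_equal(a.se, b.se)
        np.testing.assert_array_equal(a.p_value, b.p_value)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_always_zero_marker_has_p_one(self, instance):
        y, X = instance
        out = gq.bootstrap_effects(y, X, 0.5, 0.5, reps=20, seed=9)
        assert np.all(out.replicates[:, 3] == 0.0)
        assert out.se[3] == 0.0 and out.p_value[3] == 1.0

    def test_strong_marker_ranks_below_null_p(self, instance):
        y, X = instance
        out = gq.bootstrap_effects(y, X, 0.5, 0.5, reps=200, seed=9)
        null_p = np.median(out.p_value[1:3])
        assert out.p_value[0] < null_p

    def test_p_values_in_unit_interval(self, instance):
        y, X = instance
        out = gq.bootstrap_effects(y, X, 0.2, 0.5, reps=30, seed=1)
        assert np.all(out.p_value > 0.0) and np.all(out.p_value <= 1.0)
        assert np.all(out.se >= 0.0)

    def test_too_few_reps(self, instance):
        y, X = instance
        with pytest.raises(ValueError):
            gq.bootstrap_effects(y, X, 0.5, 0.5, reps=1, seed=0)
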