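import math

import numpy as np
import pytest
import statsmodels.api as sm

import tsdfit as tf
from tsdfit.data_io import IncubationGroup, TSDDataset
from tsdfit.mle_fit import binomial_neg_ln_L, make_nll, numeric_hessian
from tsdfit.reaction_norms import ModelParams
from tsdfit.synthetic_data import SimulationDesign, simulate_dataset


def _glm_logistic(ds):
    """Independent exact-MLE oracle: binomial GLM with logit link on temperature."""
    t = np.array(ds.temperatures)
    y = np.column_stack([[g.males for g in ds], [g.females for g in ds]])
    res = sm.GLM(y, sm.add_constant(t), family=sm.families.Binomial()).fit()
    b0, b1 = res.params
    S = 1.0 / b1
    return -b0 * S, S, -res.llf


class TestNegLogLikelihood:
    def test_single_mixed_group_closed_form(self):
        ds = TSDDataset([IncubationGroup(30.0, 1, 1)])
        params = ModelParams("logistic", 30.0, -0.4)
        assert tf.neg_log_likelihood(ds, params) == pytest.approx(-math.log(0.5), abs=1e-12)

    def test_binomial_term_hand_value(self):
        # 8 males, 1 female at sex ratio 0.981: -[ln C(9,8) + 8 ln 0.981 + ln 0.019]
        v = binomial_neg_ln_L(np.array([0.981]), np.array([8.0]), np.array([1.0]))
        assert v == pytest.approx(1.9195542778136687, abs=1e-10)

    def test_table1_at_published_logistic_params(self, table1):
        params = ModelParams("logistic", 30.39, -0.41)
        assert tf.neg_log_likelihood(table1, params) == pytest.approx(32.6, abs=0.05)

    def test_table1_at_published_flexit_params(self, table1):
        params = ModelParams("flexit", 30.57, -0.79, -1.72, 200.0)
        assert tf.neg_log_likelihood(table1, params) == pytest.approx(26.73, abs=0.01)

    def test_invariant_under_group_permutation(self, table1):
        params = ModelParams("logistic", 30.39, -0.41)
        rev = TSDDataset(list(reversed(table1.groups)))
        assert tf.neg_log_likelihood(rev, params) == pytest.approx(
            tf.neg_log_likelihood(table1, params), abs=1e-10
        )

    def test_split_group_shifts_only_by_coefficient(self):
        # splitting (5M, 3F) into (2M, 1F) + (3M, 2F) at one temperature changes
        # -ln L by the constant log-coefficient difference, at every parameter value
        whole = TSDDataset([IncubationGroup(30.0, 5, 3)])
        split = TSDDataset([IncubationGroup(30.0, 2, 1), IncubationGroup(30.0, 3, 2)])
        delta_coef = math.log(math.comb(8, 5)) - math.log(math.comb(3, 2) * math.comb(5, 3))
        for P, S in [(29.5, -0.3), (30.0, -0.5), (31.0, -1.2)]:
            params = ModelParams("logistic", P, S)
            d = tf.neg_log_likelihood(split, params) - tf.neg_log_likelihood(whole, params)
            assert d == pytest.approx(delta_coef, abs=1e-10)

    def test_empty_dataset_rejected(self):
        with pytest.raises(tf.FitError):
            tf.neg_log_likelihood(TSDDataset([]), ModelParams("logistic", 30.0, -0.4))


class TestFitMLE:
    def test_global_logistic_matches_glm_oracle(self, table1, global_logistic):
        P, S, nll = _glm_logistic(table1)
        assert global_logistic.params.P == pytest.approx(P, abs=1e-4)
        assert global_logistic.params.S == pytest.approx(S, abs=1e-4)
        assert global_logistic.neg_ln_L == pytest.approx(nll, abs=1e-6)

    @pytest.mark.parametrize(
        "selector",
        [
            {"rmu": "East Pacific"},
            {"country": "Costa Rica"},
            {"country": "Brazil"},
        ],
    )
    def test_subset_fits_match_glm_oracle(self, table1, selector):
        sub = table1.subset(**selector)
        fit = tf.fit_mle(sub, "logistic")
        P, S, nll = _glm_logistic(sub)
        assert fit.params.P == pytest.approx(P, abs=1e-3)
        assert fit.params.S == pytest.approx(S, abs=1e-3)
        assert fit.neg_ln_L == pytest.approx(nll, abs=1e-5)

    def test_optimizer_matches_grid_search_oracle(self, table1):
        ds = table1.subset(country="Brazil")
        fit = tf.fit_mle(ds, "logistic")
        nll = make_nll(ds, "logistic")
        P_grid = np.arange(29.5, 31.5, 0.01)
        S_grid = np.arange(-1.2, -0.05, 0.01)
        vals = np.array([[nll(np.array([P, S])) for S in S_grid] for P in P_grid])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        assert abs(fit.params.P - P_grid[i]) <= 0.01
        assert abs(fit.params.S - S_grid[j]) <= 0.01
        assert fit.neg_ln_L <= vals[i, j] + 1e-8

    def test_flexit_nests_logistic(self, global_logistic, global_flexit):
        assert global_flexit.neg_ln_L <= global_logistic.neg_ln_L + 1e-8

    def test_flexit_high_cv_flagged(self, global_flexit):
        # the upper-asymptote shape is essentially unidentified on these data
        assert global_flexit.cv[3] > 1.0
        assert any("K2" in w for w in global_flexit.warnings)

    def test_all_one_sex_refused_with_bayesian_pointer(self):
        ds = TSDDataset([IncubationGroup(26.0, 10, 0), IncubationGroup(28.0, 12, 0)])
        with pytest.raises(tf.FitError, match="Bayesian"):
            tf.fit_mle(ds, "logistic")

    def test_few_mixed_groups_warns(self, table1):
        mexico = table1.subset(country="Mexico")  # a single mixed-sex temperature
        with pytest.warns(UserWarning, match="mixed-sex"):
            tf.fit_mle(mexico, "logistic")

    def test_parameter_recovery_within_3se(self, table1):
        truth = ModelParams("logistic", 30.0, -0.4)
        design = SimulationDesign(
            temperatures=list(np.linspace(27.0, 33.0, 10)),
            eggs_per_temperature=[30] * 10,
            truth=truth,
            seed=77,
        )
        fit = tf.fit_mle(simulate_dataset(design), "logistic")
        assert abs(fit.params.P - truth.P) <= 3.0 * fit.se[0]
        assert abs(fit.params.S - truth.S) <= 3.0 * fit.se[1]

    def test_init_fast_path_agrees_with_multistart(self, table1):
        full = tf.fit_mle(table1, "logistic")
        fast = tf.fit_mle(table1, "logistic", init=full.params, multi_start=False)
        assert fast.neg_ln_L == pytest.approx(full.neg_ln_L, abs=1e-8)


class TestHessianCovariance:
    def test_quadratic_toy_recovers_analytic_inverse(self):
        A = np.array([[2.0, 0.3], [0.3, 1.0]])
        f = lambda x: 0.5 * x @ A @ x
        H = numeric_hessian(f, np.array([0.7, -0.2]))
        assert np.allclose(H, A, atol=1e-5)
        assert np.allclose(np.linalg.inv(H), np.linalg.inv(A), atol=1e-4)

    def test_global_logistic_standard_errors(self, global_logistic):
        assert global_logistic.se[0] == pytest.approx(0.09, abs=0.01)
        assert global_logistic.se[1] == pytest.approx(0.05, abs=0.01)
        assert global_logistic.hessian_invertible

    def test_covariance_symmetric_and_consistent_with_se(self, global_logistic):
        cov = global_logistic.covariance
        assert np.allclose(cov, cov.T)
        assert np.allclose(global_logistic.se, np.sqrt(np.diag(cov)))
        assert np.allclose(
            global_logistic.cv,
            global_logistic.se / np.abs(global_logistic.params.to_array()),
        )

    def test_matches_glm_covariance(self, table1, global_logistic):
        # delta-method transform of the GLM (intercept, slope) covariance
        t = np.array(table1.temperatures)
        y = np.column_stack([[g.males for g in table1], [g.females for g in table1]])
        res = sm.GLM(y, sm.add_constant(t), family=sm.families.Binomial()).fit()
        b0, b1 = res.params
        J = np.array([[-1.0 / b1, b0 / b1**2], [0.0, -1.0 / b1**2]])
        cov_PS = J @ res.cov_params() @ J.T
        assert np.allclose(global_logistic.covariance, cov_PS, rtol=1e-3, atol=1e-6)
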