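import numpy as np
import pytest
from scipy import stats

import tsdfit as tf
from tsdfit.data_io import IncubationGroup, TSDDataset
from tsdfit.mle_fit import FitResult
from tsdfit.model_selection import saturated_ln_L
from tsdfit.reaction_norms import ModelParams
from tsdfit.synthetic_data import SimulationDesign, simulate_dataset


class TestDevianceGOF:
    def test_global_logistic(self, global_logistic, table1):
        g = tf.deviance_gof(global_logistic, table1)
        assert g.deviance == pytest.approx(45.68, abs=0.01)
        assert g.df == 38
        assert g.p_chi2 == pytest.approx(0.183117, abs=1e-4)

    def test_identity_with_likelihood_routine(self, global_logistic, table1):
        g = tf.deviance_gof(global_logistic, table1)
        direct = 2.0 * (saturated_ln_L(table1) + global_logistic.neg_ln_L)
        assert g.deviance == pytest.approx(direct, abs=1e-10)

    def test_matches_glm_deviance(self, east_pacific, ep_logistic):
        import statsmodels.api as sm

        t = np.array(east_pacific.temperatures)
        y = np.column_stack([[g.males for g in east_pacific], [g.females for g in east_pacific]])
        res = sm.GLM(y, sm.add_constant(t), family=sm.families.Binomial()).fit()
        g = tf.deviance_gof(ep_logistic, east_pacific)
        assert g.deviance == pytest.approx(res.deviance, abs=1e-6)
        assert g.df == len(east_pacific) - 2

    def test_perfect_fit_has_zero_deviance(self):
        # a logistic that reproduces the observed proportions exactly
        ds = TSDDataset([IncubationGroup(28.0, 10, 0), IncubationGroup(32.0, 0, 10)])
        fit = FitResult(
            params=ModelParams("logistic", 30.0, -0.1),
            neg_ln_L=tf.neg_log_likelihood(ds, ModelParams("logistic", 30.0, -0.1)),
            covariance=np.zeros((2, 2)), se=np.zeros(2), cv=np.zeros(2),
            n_groups=2, converged=True,
        )
        assert tf.deviance_gof(fit, ds).deviance == pytest.approx(0.0, abs=1e-6)

    def test_overparameterized_rejected(self, global_flexit):
        tiny = TSDDataset([IncubationGroup(30.0, 3, 2)])
        with pytest.raises(ValueError, match="over-parameterized"):
            tf.deviance_gof(global_flexit, tiny)


class TestNullDevianceTest:
    def test_null_mean_close_to_df_at_large_counts(self):
        truth = ModelParams("logistic", 30.0, -0.4)
        ds = simulate_dataset(
            SimulationDesign([27, 28, 29, 30, 31, 32, 33], [500] * 7, truth, 1)
        )
        fit = tf.fit_mle(ds, "logistic")
        g = tf.null_deviance_test(fit, ds, n_rep=200, seed=2)
        assert g.null_deviances.mean() == pytest.approx(g.df, rel=0.2)
        assert 0.0 <= g.p_random <= 1.0
        assert g.n_failed == 0

    def test_p_random_uniform_under_well_specified_model(self):
        # validity of the parametric bootstrap: refitting data simulated from
        # the fitted model yields approximately uniform bootstrap p-values
        truth = ModelParams("logistic", 30.0, -0.4)
        temps, eggs = [27, 28, 29, 30, 31, 32], [25] * 6
        rng = np.random.default_rng(4)
        pvals = []
        for s in rng.integers(0, 2**31 - 1, 40):
            sim = simulate_dataset(SimulationDesign(temps, eggs, truth, int(s)))
            try:
                f = tf.fit_mle(sim, "logistic")
            except tf.FitError:
                continue
            pvals.append(tf.null_deviance_test(f, sim, n_rep=80, seed=int(s)).p_random)
        assert len(pvals) >= 35
        ks = stats.kstest(np.asarray(pvals), "uniform")
        assert ks.pvalue > 0.01

    def test_seeded_runs_reproduce(self, costa_rica):
        fit = tf.fit_mle(costa_rica, "logistic")
        a = tf.null_deviance_test(fit, costa_rica, n_rep=50, seed=9)
        b = tf.null_deviance_test(fit, costa_rica, n_rep=50, seed=9)
        assert np.array_equal(a.null_deviances, b.null_deviances)
        assert a.p_random == b.p_random


class TestInformationCriteria:
    def test_global_table(self, global_logistic, global_flexit):
        table = tf.information_criteria([global_logistic, global_flexit]).table
        assert table.loc["logistic", "AICc"] == pytest.approx(69.52, abs=0.01)
        assert table.loc["flexit", "dAICc"] == 0.0
        assert table["Akaike weight"].sum() == pytest.approx(1.0)
        assert table.loc["flexit", "Akaike weight"] == pytest.approx(0.97, abs=0.01)

    def test_aicc_uses_listed_group_count(self, global_logistic, global_flexit):
        out = tf.information_criteria([global_logistic, global_flexit])
        assert out.n_for_aicc == 40
        row = out.table.loc["logistic"]
        assert row["AICc"] == pytest.approx(row["AIC"] + 12.0 / 37.0, abs=1e-9)

    def test_equal_fits_share_weight(self, global_logistic):
        out = tf.information_criteria([global_logistic, global_logistic], ["a", "b"])
        assert np.allclose(out.table["Akaike weight"], [0.5, 0.5])

    def test_single_model_gets_unit_weight(self, global_logistic):
        out = tf.information_criteria([global_logistic])
        assert out.table["Akaike weight"].iloc[0] == pytest.approx(1.0)

    def test_weights_invariant_to_criterion_shift(self, global_logistic, global_flexit):
        out = tf.information_criteria([global_logistic, global_flexit])
        d = out.table["AICc"] - out.table["AICc"].min()
        w = np.exp(-(d + 123.0 - 123.0) / 2)
        assert np.allclose(out.table["Akaike weight"], w / w.sum())

    def test_different_datasets_rejected(self, global_logistic, ep_logistic):
        with pytest.raises(ValueError, match="same dataset"):
            tf.information_criteria([global_logistic, ep_logistic])


class TestGroupedVsSeparated:
    def test_east_pacific_sample_sizes(self, table1):
        cr = table1.subset(country="Costa Rica")
        mx = table1.subset(country="Mexico")
        comp = tf.grouped_vs_separated([cr, mx], "logistic")
        assert comp.grouped["n"] == 15  # distinct pooled temperatures
        assert comp.separated["n"] == 7 + 12  # per-dataset distinct counts
        assert comp.grouped["p"] == 2 and comp.separated["p"] == 4
        assert comp.w_values["grouped"] + comp.w_values["separated"] == pytest.approx(1.0)

    def test_grouped_bic_consistent_with_pooled_fit(self, table1, ep_logistic):
        cr = table1.subset(country="Costa Rica")
        mx = table1.subset(country="Mexico")
        comp = tf.grouped_vs_separated([cr, mx], "logistic")
        expect = 2.0 * ep_logistic.neg_ln_L + 2.0 * np.log(15)
        assert comp.grouped["BIC"] == pytest.approx(expect, abs=1e-6)

    def test_identical_copies_always_grouped(self, costa_rica):
        a = TSDDataset(list(costa_rica.groups), label="a")
        b = TSDDataset(list(costa_rica.groups), label="b")
        comp = tf.grouped_vs_separated([a, b], "logistic")
        assert comp.w_values["grouped"] > 0.5
        # pooled -lnL differs from the sum only through binomial coefficients;
        # the penalty gap is what decides
        assert comp.delta > 0

    def test_all_one_sex_dataset_aborts_with_report(self, costa_rica):
        allmale = TSDDataset(
            [IncubationGroup(26.0, 10, 0), IncubationGroup(27.0, 8, 0)], label="males-only"
        )
        with pytest.raises(tf.FitError, match="males-only"):
            tf.grouped_vs_separated([costa_rica, allmale], "logistic")

    def test_needs_two_datasets(self, costa_rica):
        with pytest.raises(ValueError):
            tf.grouped_vs_separated([costa_rica], "logistic")

    def test_group_count_convention_option(self, table1):
        cr = table1.subset(country="Costa Rica")
        mx = table1.subset(country="Mexico")
        comp = tf.grouped_vs_separated([cr, mx], "logistic", n_convention="groups")
        assert comp.grouped["n"] == 22
        assert comp.separated["n"] == 22
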