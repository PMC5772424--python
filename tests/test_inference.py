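import numpy as np
import pandas as pd
import pytest

from borneoabc.demography import ModelSpec, PriorSpec
from borneoabc.inference import (LayoutMismatchError, ParameterPosterior,
                                 ReferenceTable, bayes_factors, hpd_interval,
                                 loclinear_adjust, marginal_density_pvalue,
                                 model_posterior_logistic,
                                 model_posterior_rejection,
                                 posterior_summaries, reject,
                                 standardize_and_distance, transforms_for,
                                 weighted_quantile)


def make_table(stats: np.ndarray, models=None, params=None,
               stat_names=None) -> ReferenceTable:
    stats = np.atleast_2d(np.asarray(stats, float))
    n, d = stats.shape
    cols = stat_names or [f"s{i}" for i in range(d)]
    models = np.asarray(models if models is not None else ["M"] * n)
    params = params if params is not None else pd.DataFrame(
        {"theta": np.zeros(n)})
    return ReferenceTable(models, params, pd.DataFrame(stats, columns=cols))


def obs_vector(values, names=None):
    values = np.atleast_1d(np.asarray(values, float))
    names = names or [f"s{i}" for i in range(len(values))]
    return pd.Series(values, index=names)


class TestDistance:
    def test_matching_row_has_zero_distance(self):
        rng = np.random.default_rng(60)
        stats = rng.normal(size=(50, 3))
        d = standardize_and_distance(make_table(stats),
                                     obs_vector(stats[17], ["s0", "s1", "s2"]))
        assert d[17] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_midpoint(self):
        d = standardize_and_distance(make_table([[1.0], [3.0]]),
                                     obs_vector([2.0]))
        assert d[0] == pytest.approx(d[1])

    def test_mad_scaling_removes_units(self):
        """Multiplying one statistic by 10 everywhere leaves distances
        unchanged."""
        rng = np.random.default_rng(61)
        stats = rng.normal(size=(200, 3))
        obs = rng.normal(size=3)
        d1 = standardize_and_distance(make_table(stats), obs_vector(obs))
        stats2 = stats.copy()
        stats2[:, 1] *= 10
        obs2 = obs.copy()
        obs2[1] *= 10
        d2 = standardize_and_distance(make_table(stats2), obs_vector(obs2))
        assert np.allclose(d1, d2)

    def test_layout_mismatch_names_columns(self):
        with pytest.raises(LayoutMismatchError, match="s1"):
            standardize_and_distance(make_table([[1.0, 2.0]]),
                                     obs_vector([1.0], ["s0"]))


class TestReject:
    def test_tolerance_one_keeps_everything(self):
        rng = np.random.default_rng(62)
        table = make_table(rng.normal(size=(30, 2)))
        assert reject(table, obs_vector([0, 0]), 1.0).n_retained == 30

    def test_retained_count_is_ceiling(self):
        rng = np.random.default_rng(63)
        table = make_table(rng.normal(size=(1000, 2)))
        assert reject(table, obs_vector([0, 0]), 0.01).n_retained == 10

    def test_smallest_distances_kept(self):
        table = make_table([[1.0], [2.0], [3.0], [4.0], [5.0]])
        kept = reject(table, obs_vector([0.9]), 0.4)
        assert sorted(kept.indices.tolist()) == [0, 1]

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError):
            reject(make_table([[1.0]]), obs_vector([1.0]), 0.0)


class TestModelPosterior:
    def test_rejection_proportions(self):
        table = make_table(np.zeros((4, 1)), models=["A", "A", "A", "B"])
        probs = model_posterior_rejection(reject(table, obs_vector([0]), 1.0))
        assert probs["A"] == 0.75 and probs["B"] == 0.25

    def test_rejection_matches_label_counter(self):
        """Oracle equivalence: proportions equal brute-force label counts
        on 100 random retained sets."""
        rng = np.random.default_rng(64)
        for _ in range(100):
            labels = rng.choice(list("ABC"), size=rng.integers(3, 40))
            table = make_table(np.zeros((len(labels), 1)), models=labels)
            probs = model_posterior_rejection(
                reject(table, obs_vector([0]), 1.0))
            for m in "ABC":
                expected = sum(1 for x in labels if x == m) / len(labels)
                assert probs.get(m, 0.0) == pytest.approx(expected)

    def test_logistic_separable_case(self):
        """Model A lives at negative statistic values, B at positive;
        an observation at -2 is almost surely from A."""
        rng = np.random.default_rng(65)
        stats = np.concatenate([rng.uniform(-3, 0, 1000),
                                rng.uniform(0, 3, 1000)])[:, None]
        table = make_table(stats, models=["A"] * 1000 + ["B"] * 1000)
        probs = model_posterior_logistic(table, obs_vector([-2.0]), 0.5)
        assert probs["A"] > 0.99

    def test_logistic_exchangeable_case(self):
        """Two models simulated identically: the posterior hovers around
        1/2 on average."""
        rng = np.random.default_rng(66)
        draws = []
        for _ in range(50):
            stats = rng.normal(size=(400, 2))
            table = make_table(stats, models=["A"] * 200 + ["B"] * 200)
            probs = model_posterior_logistic(table, obs_vector([0.0, 0.0]),
                                             0.5)
            draws.append(probs["A"])
        assert 0.4 < np.mean(draws) < 0.6

    def test_single_model_gets_probability_one(self):
        table = make_table(np.zeros((5, 1)), models=["A"] * 5)
        probs = model_posterior_logistic(table, obs_vector([0.0]), 1.0)
        assert probs["A"] == 1.0


class TestBayesFactors:
    def test_ratio(self):
        bf = bayes_factors(pd.Series({"A": 0.9, "B": 0.1}))
        assert bf.loc["A", "B"] == pytest.approx(9.0)

    def test_equal_probabilities(self):
        bf = bayes_factors(pd.Series({"A": 0.5, "B": 0.5}))
        assert np.allclose(bf.to_numpy(), 1.0)

    def test_zero_probability_gives_infinity(self):
        bf = bayes_factors(pd.Series({"A": 1.0, "B": 0.0}))
        assert np.isinf(bf.loc["A", "B"])

    def test_reciprocal_identity(self):
        rng = np.random.default_rng(67)
        for _ in range(20):
            p = rng.dirichlet(np.ones(4)) + 1e-6
            p /= p.sum()
            bf = bayes_factors(pd.Series(p, index=list("ABCD"))).to_numpy()
            assert np.allclose(bf * bf.T, 1.0)


class TestMarginalDensity:
    def test_observation_at_the_mode_scores_high(self):
        rng = np.random.default_rng(68)
        table = make_table(rng.normal(size=(1000, 3)))
        retained = reject(table, obs_vector([0.0, 0.0, 0.0]), 1.0)
        assert marginal_density_pvalue(retained) > 0.8

    def test_far_outlier_scores_low(self):
        rng = np.random.default_rng(69)
        table = make_table(rng.normal(size=(1000, 2)))
        retained = reject(table, obs_vector([10.0, 10.0]), 1.0)
        assert marginal_density_pvalue(retained) < 0.01

    def test_pvalue_is_a_fraction(self):
        rng = np.random.default_rng(70)
        for _ in range(5):
            table = make_table(rng.normal(size=(200, 2)))
            retained = reject(table, obs_vector(rng.normal(size=2)), 0.5)
            assert 0.0 <= marginal_density_pvalue(retained) <= 1.0


def linear_spec():
    return ModelSpec("ID", {
        "N_anc": PriorSpec("loguniform", 2, 4),
        "N_cur": PriorSpec("loguniform", 2, 3),
        "T_shrink": PriorSpec("uniform", 0, 1000),
        "mu": PriorSpec("loguniform", -5, -3),
        "p_gsm": PriorSpec("uniform", 0, 0.3),
    })


class TestLocLinear:
    def test_noise_free_relation_collapses_to_truth(self):
        """A parameter that is an exact linear function of one statistic is
        recovered exactly at the observed point."""
        rng = np.random.default_rng(71)
        stats = rng.uniform(0, 500, size=(400, 1))
        t = 1.5 * stats[:, 0] + 20.0
        table = make_table(stats, params=pd.DataFrame({"T_shrink": t}))
        retained = reject(table, obs_vector([200.0]), 1.0)
        post = loclinear_adjust(retained, linear_spec(),
                                param_names=("T_shrink",))
        vals = post.samples["T_shrink"].to_numpy()
        assert np.allclose(vals, 1.5 * 200 + 20, atol=1e-6)
        assert vals.var() < 1e-10 * t.var()

    def test_uninformative_statistics_leave_prior_untouched(self):
        from scipy import stats as sps
        rng = np.random.default_rng(72)
        stats = rng.normal(size=(2000, 2))
        t = rng.uniform(0, 1000, size=2000)
        table = make_table(stats, params=pd.DataFrame({"T_shrink": t}))
        retained = reject(table, obs_vector([0.0, 0.0]), 1.0)
        post = loclinear_adjust(retained, linear_spec(),
                                param_names=("T_shrink",))
        res = sps.ks_2samp(post.samples["T_shrink"].to_numpy(), t)
        assert res.pvalue > 0.01

    def test_constant_parameter_stays_constant(self):
        rng = np.random.default_rng(73)
        stats = rng.normal(size=(100, 2))
        table = make_table(stats,
                           params=pd.DataFrame({"T_shrink": np.full(100, 7.0)}))
        retained = reject(table, obs_vector([0.0, 0.0]), 1.0)
        post = loclinear_adjust(retained, linear_spec(),
                                param_names=("T_shrink",))
        assert np.allclose(post.samples["T_shrink"], 7.0)

    def test_too_few_rows_is_an_error(self):
        rng = np.random.default_rng(74)
        table = make_table(rng.normal(size=(3, 4)),
                           params=pd.DataFrame({"T_shrink": [1.0, 2.0, 3.0]}))
        retained = reject(table, obs_vector([0.0] * 4), 1.0)
        with pytest.raises(ValueError, match="too few"):
            loclinear_adjust(retained, linear_spec(),
                             param_names=("T_shrink",))

    def test_log_scale_parameters_adjusted_on_log_scale(self):
        """A loguniform parameter exactly linear in a statistic on the
        log10 scale collapses to the right back-transformed value."""
        rng = np.random.default_rng(75)
        stats = rng.uniform(-1, 1, size=(300, 1))
        log_n = 3.0 + 0.5 * stats[:, 0]
        table = make_table(stats,
                           params=pd.DataFrame({"N_anc": 10.0 ** log_n}))
        retained = reject(table, obs_vector([0.3]), 1.0)
        post = loclinear_adjust(retained, linear_spec(),
                                param_names=("N_anc",))
        assert np.allclose(post.samples["N_anc"], 10 ** 3.15, rtol=1e-6)


class TestSummaries:
    def make_posterior(self, x, w=None):
        x = np.asarray(x, float)
        w = np.ones(len(x)) if w is None else np.asarray(w, float)
        tr = transforms_for(linear_spec())
        return ParameterPosterior(pd.DataFrame({"T_shrink": x}), w, tr)

    def test_equal_weight_mean_and_median(self):
        summ = posterior_summaries(self.make_posterior([1.0, 2.0, 3.0]))
        assert summ.loc["T_shrink", "mean"] == pytest.approx(2.0)
        assert summ.loc["T_shrink", "median"] == pytest.approx(2.0)

    def test_hpd_of_standard_normal(self):
        rng = np.random.default_rng(76)
        x = rng.standard_normal(100_000)
        lo, hi = hpd_interval(x, np.ones_like(x), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_point_mass_has_degenerate_summaries(self):
        summ = posterior_summaries(self.make_posterior([5.0] * 20))
        row = summ.loc["T_shrink"]
        assert np.allclose(row.to_numpy(), 5.0)
        assert row["hpd_high"] - row["hpd_low"] == 0.0

    def test_weighted_quantile_respects_weights(self):
        x = np.array([0.0, 10.0])
        w = np.array([9.0, 1.0])
        assert weighted_quantile(x, w, 0.5) < 2.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            self.make_posterior([1.0, 2.0], w=[1.0, -0.5])
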