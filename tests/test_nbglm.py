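"""Many-species NB GLMs: fitting, AIC selection, sum-of-LR bootstrap, residuals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from antscape.nbglm import (
    backward_stepwise_aic,
    build_design,
    dunn_smyth_residuals,
    fit_many_nb,
    nb_fit_batch,
    sum_of_lr_test,
)


def _nb_counts(rng, mu, theta):
    return rng.negative_binomial(theta, theta / (theta + mu))


def _drop_empty_sites(counts, env, offset):
    """Mirror the pipeline: empty sites are excluded before count models."""
    keep = counts.sum(axis=1).to_numpy() > 0
    return (counts.loc[keep].reset_index(drop=True),
            env.loc[keep].reset_index(drop=True), np.asarray(offset)[keep])


class TestDesign:
    def test_categorical_reference_is_first_sorted_level(self):
        env = pd.DataFrame({"management": ["pasture", "meadow", "pasture"]})
        d = build_design(env)
        assert d.columns == ["Intercept", "management[pasture]"]

    def test_continuous_standardized_with_metadata(self):
        env = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        d = build_design(env)
        assert d.X[:, 1].mean() == pytest.approx(0.0, abs=1e-12)
        assert d.X[:, 1].std() == pytest.approx(1.0, rel=1e-12)
        mu, sd = d.standardization["x"]
        assert (mu, sd) == (2.5, pytest.approx(np.sqrt(1.25)))

    def test_interaction_columns(self):
        env = pd.DataFrame({"x": [1.0, 2, 3, 4], "m": ["a", "b", "a", "b"]})
        d = build_design(env, terms=["x", "m", "x:m"])
        assert "x:m[b]" in d.columns
        j = d.columns.index("x:m[b]")
        np.testing.assert_allclose(d.X[:, j], d.X[:, 1] * d.X[:, 2])

    def test_subset_keeps_intercept(self):
        env = pd.DataFrame({"x": [1.0, 2, 3], "y": [3.0, 1, 2]})
        d = build_design(env)
        sub = d.subset(["y"])
        assert sub.columns == ["Intercept", "y"]


class TestFit:
    def test_constant_counts_intercept_is_log_mean(self):
        n, c = 30, 4
        counts = pd.DataFrame({"a": [c] * n, "b": [c] * n})
        env = pd.DataFrame({"x": np.linspace(-1, 1, n)})
        fit = fit_many_nb(counts, env, np.zeros(n), terms=[])
        assert fit.coef[:, 0] == pytest.approx([np.log(c)] * 2, abs=1e-6)

    def test_matches_statsmodels_univariate_oracle(self, rng):
        from statsmodels.discrete.discrete_model import NegativeBinomial

        n = 60
        x = rng.normal(size=n)
        off = rng.normal(scale=0.2, size=n)
        X = np.column_stack([np.ones(n), x])
        counts = pd.DataFrame({
            s: _nb_counts(rng, np.exp(off + 0.8 + b * x), 2.0)
            for s, b in [("a", 0.5), ("b", -0.4)]
        })
        env = pd.DataFrame({"x": x})
        counts, env, off = _drop_empty_sites(counts, env, off)
        fit = fit_many_nb(counts, env, off, terms=["x"])
        # the design standardizes x; refit statsmodels on the same matrix
        for j, sp in enumerate(fit.species):
            sm = NegativeBinomial(counts[sp].to_numpy(), fit.design.X, offset=off).fit(
                disp=0, maxiter=300)
            np.testing.assert_allclose(fit.coef[j], sm.params[:-1], atol=5e-4)
            assert fit.loglik[j] == pytest.approx(sm.llf, abs=1e-5)

    def test_parameter_recovery_large_n(self, rng):
        n, m = 200, 6
        x = rng.normal(size=n)
        beta = rng.uniform(-0.8, 0.8, size=m)
        theta = 2.0
        counts = pd.DataFrame({
            f"s{j}": _nb_counts(rng, np.exp(1.0 + beta[j] * x), theta) for j in range(m)
        })
        env = pd.DataFrame({"x": x})
        fit = fit_many_nb(counts, env, np.zeros(n))
        sd_x = x.std(ddof=0)
        recovered = fit.coef[:, 1] / sd_x  # undo standardization
        assert np.abs(recovered - beta).max() < 0.25
        assert np.median(np.abs(fit.theta - theta)) < 1.5

    def test_all_zero_species_dropped_with_warning(self, rng):
        counts = pd.DataFrame({"a": [1, 2, 3, 1, 2], "z": [0] * 5})
        env = pd.DataFrame({"x": np.arange(5.0)})
        with pytest.warns(UserWarning, match="z"):
            fit = fit_many_nb(counts, env, np.zeros(5))
        assert fit.species == ["a"]
        assert fit.dropped_species == ["z"]

    def test_all_zero_site_rejected(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [2, 0]})
        env = pd.DataFrame({"x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="all-zero sites"):
            fit_many_nb(counts, env, np.zeros(2))

    def test_offset_contract(self, rng):
        """offset + ln 2 shifts intercepts by -ln 2, slopes unchanged."""
        n = 80
        x = rng.normal(size=n)
        counts = pd.DataFrame({"a": _nb_counts(rng, np.exp(1.2 + 0.5 * x), 2.0)})
        env = pd.DataFrame({"x": x})
        counts, env, _ = _drop_empty_sites(counts, env, np.zeros(n))
        n2 = len(counts)
        f1 = fit_many_nb(counts, env, np.zeros(n2))
        f2 = fit_many_nb(counts, env, np.full(n2, np.log(2.0)))
        assert f2.coef[0, 0] - f1.coef[0, 0] == pytest.approx(-np.log(2.0), abs=1e-6)
        assert f2.coef[0, 1] == pytest.approx(f1.coef[0, 1], abs=1e-6)

    def test_poisson_limit_on_equidispersed_data(self, rng):
        import statsmodels.api as sm

        n = 300
        x = rng.normal(size=n)
        mu = np.exp(1.0 + 0.4 * x)
        y = rng.poisson(mu)
        counts = pd.DataFrame({"a": y})
        env = pd.DataFrame({"x": x})
        counts, env, off = _drop_empty_sites(counts, env, np.zeros(n))
        fit = fit_many_nb(counts, env, off)
        pois = sm.GLM(counts["a"].to_numpy(), fit.design.X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.coef[0], pois.params, atol=5e-3)


class TestStepwise:
    def test_noise_predictor_eliminated(self, rng):
        n = 300
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        counts = pd.DataFrame({
            f"s{j}": _nb_counts(rng, np.exp(1.0 + 0.9 * x), 2.0) for j in range(4)
        })
        env = pd.DataFrame({"x": x, "noise": noise})
        counts, env, off = _drop_empty_sites(counts, env, np.zeros(n))
        full = fit_many_nb(counts, env, off)
        reduced, path = backward_stepwise_aic(full)
        assert reduced.design.term_names == ["x"]
        assert path[-1]["action"] == "drop noise"

    def test_no_candidates_returns_unchanged(self, rng):
        counts = pd.DataFrame({"a": _nb_counts(rng, np.full(30, 3.0), 2.0)})
        env = pd.DataFrame({"x": np.linspace(0, 1, 30)})
        counts, env, off = _drop_empty_sites(counts, env, np.zeros(30))
        fit = fit_many_nb(counts, env, off, terms=[])
        reduced, path = backward_stepwise_aic(fit)
        assert reduced.design.term_names == []
        assert len(path) == 1

    def test_redundant_duplicate_predictor_dropped(self, rng):
        n = 200
        x = rng.normal(size=n)
        counts = pd.DataFrame({
            f"s{j}": _nb_counts(rng, np.exp(1.0 + 0.8 * x), 2.0) for j in range(3)
        })
        env = pd.DataFrame({"x": x, "x_copy": x})
        counts, env, off = _drop_empty_sites(counts, env, np.zeros(n))
        with pytest.warns(UserWarning, match="rank deficient"):
            full = fit_many_nb(counts, env, off)
        reduced, _ = backward_stepwise_aic(full)
        assert len(reduced.design.term_names) == 1


class TestSumOfLR:
    def _fits(self, rng, n=40, m=3, beta=0.0):
        x = rng.normal(size=n)
        counts = pd.DataFrame({
            f"s{j}": _nb_counts(rng, np.exp(1.0 + beta * x), 2.0) for j in range(m)
        })
        counts, env, off = _drop_empty_sites(counts, pd.DataFrame({"x": x}), np.zeros(n))
        full = fit_many_nb(counts, env, off)
        red = fit_many_nb(counts, env, off, design=full.design.subset([]))
        return full, red

    def test_identical_models_give_zero_lr_p_one(self, rng):
        full, _ = self._fits(rng)
        res = sum_of_lr_test(full, full, n_boot=99, seed=1)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_statistic_is_sum_of_per_species_lr(self, rng):
        full, red = self._fits(rng, beta=0.5)
        res = sum_of_lr_test(full, red, n_boot=99, seed=2)
        # independent per-species route: separate univariate fits
        per = []
        for j, sp in enumerate(full.species):
            y = full.Y[j][None, :]
            _, _, llf, _ = nb_fit_batch(full.design.X, y, full.offset)
            _, _, llr, _ = nb_fit_batch(red.design.X, y, red.offset)
            per.append(max(2.0 * (llf[0] - llr[0]), 0.0))
        assert res.statistic == pytest.approx(sum(per), abs=1e-8)
        assert res.per_species_lr.to_numpy() == pytest.approx(np.array(per), abs=1e-8)

    def test_p_value_lower_bound_and_determinism(self, rng):
        full, red = self._fits(rng, beta=1.5)
        res1 = sum_of_lr_test(full, red, n_boot=99, seed=7)
        res2 = sum_of_lr_test(full, red, n_boot=99, seed=7)
        assert res1.p_value == res2.p_value
        assert res1.p_value >= 1.0 / 100.0
        assert res1.p_value <= 1.0

    def test_non_nested_rejected(self, rng):
        full, red = self._fits(rng)
        with pytest.raises(ValueError, match="subset"):
            sum_of_lr_test(red, full)

    def test_copula_mode_runs_and_is_seeded(self, rng):
        full, red = self._fits(rng, beta=0.4)
        r1 = sum_of_lr_test(full, red, n_boot=49, seed=3, correlation="copula")
        r2 = sum_of_lr_test(full, red, n_boot=49, seed=3, correlation="copula")
        assert r1.p_value == r2.p_value
        assert r1.statistic == pytest.approx(
            sum_of_lr_test(full, red, n_boot=49, seed=4).statistic)


class TestDunnSmyth:
    def test_seeded_determinism(self, rng):
        n = 50
        x = rng.normal(size=n)
        counts = pd.DataFrame({"a": _nb_counts(rng, np.exp(1.0 + 0.3 * x), 2.0),
                               "b": _nb_counts(rng, np.exp(0.5), 2.0)})
        env = pd.DataFrame({"x": x})
        fit = fit_many_nb(counts, env, np.zeros(n))
        r1 = dunn_smyth_residuals(fit, seed=5)
        r2 = dunn_smyth_residuals(fit, seed=5)
        pd.testing.assert_frame_equal(r1, r2)
        assert r1.shape == (n, 2)

    def test_residuals_normal_under_correct_model(self, rng):
        n = 400
        x = rng.normal(size=n)
        # means kept well above zero so no sites need dropping (conditioning
        # on non-empty sites would itself distort the residual distribution)
        counts = pd.DataFrame({"a": _nb_counts(rng, np.exp(2.5 + 0.3 * x), 3.0)})
        env = pd.DataFrame({"x": x})
        counts, env, off = _drop_empty_sites(counts, env, np.zeros(n))
        fit = fit_many_nb(counts, env, off)
        res = dunn_smyth_residuals(fit, seed=6).to_numpy().ravel()
        assert stats.shapiro(res).pvalue > 0.01
        assert abs(res.mean()) < 0.15
        assert abs(res.std() - 1.0) < 0.15
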