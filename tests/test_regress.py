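import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from synpi.regress import (chromosome_covariate_model, decile_stratified_regression,
                           ols, pcr, spearman)


class TestSpearman:
    def test_monotone_transform_is_one(self, rng):
        x = rng.random(30)
        assert spearman(x, np.exp(3 * x)).rho == pytest.approx(1.0)
        assert spearman(x, -x ** 3).rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # sum d^2 = 4 -> 1 - 6*4/(5*24) = 0.8 (verified against scipy)
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        res = spearman(x, y)
        assert res.rho == pytest.approx(0.8)
        assert res.rho == pytest.approx(st.spearmanr(x, y).statistic)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, 40).astype(float)  # heavy ties
        y = x * 0.5 + rng.integers(0, 4, 40)
        ours = spearman(x, y)
        ref = st.spearmanr(x, y)
        assert ours.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_equals_pearson_of_ranks(self, rng):
        x = rng.integers(0, 10, 60).astype(float)
        y = rng.integers(0, 10, 60).astype(float)
        rho = spearman(x, y).rho
        assert rho == pytest.approx(np.corrcoef(st.rankdata(x), st.rankdata(y))[0, 1])

    def test_exact_permutation_p_small_n(self):
        # n=5: p is the exact share of rank permutations at least as extreme,
        # counted here by explicit enumeration
        from itertools import permutations as perms

        x, y = [1.0, 2, 3, 4, 5], [1.0, 2, 3, 5, 4]
        res = spearman(x, y)
        obs = np.corrcoef(st.rankdata(x), st.rankdata(y))[0, 1]
        count = sum(
            abs(np.corrcoef(st.rankdata(x), st.rankdata(p))[0, 1]) >= abs(obs) - 1e-12
            for p in perms(y))
        assert res.p_value == pytest.approx(count / 120, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestOls:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        res = ols(2 * x + 1, pd.DataFrame({"x": x}))
        assert res.coef("x") == pytest.approx(2.0)
        assert res.coef("const") == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_orthogonal_response(self, rng):
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        res = ols(y, pd.DataFrame({"x": x}))
        assert abs(res.t("x")) < 3
        assert res.r2 < 0.01

    def test_against_normal_equations_oracle(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        y = rng.standard_normal(10)
        res = ols(y, X)
        D = np.column_stack([np.ones(10), X.to_numpy()])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert res.coef("const") == pytest.approx(beta[0], abs=1e-10)
        assert res.coef("a") == pytest.approx(beta[1], abs=1e-10)
        assert res.coef("b") == pytest.approx(beta[2], abs=1e-10)
        resid = y - D @ beta
        sigma2 = resid @ resid / (10 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(D.T @ D)))
        assert res.params["se"].to_numpy() == pytest.approx(se, abs=1e-10)
        # F statistic and df follow (p, n-p-1)
        assert (res.df_model, res.df_resid) == (2, 7)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.standard_normal(50)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="x2"):
            ols(rng.standard_normal(50), X)


class TestPcr:
    def test_single_predictor_equals_simple_regression(self, rng):
        x = rng.standard_normal(200)
        y = 0.5 * x + rng.standard_normal(200)
        X = pd.DataFrame({"x": x})
        assert pcr(y, X).total_r2 == pytest.approx(ols(y, X).r2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_r2_decomposition_sums_to_ols(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 400, 5
        L = rng.standard_normal((p, p)) * 0.5 + np.eye(p)
        X = pd.DataFrame(rng.standard_normal((n, p)) @ L,
                         columns=list("abcde"))
        y = X.to_numpy() @ rng.standard_normal(p) + rng.standard_normal(n)
        res = pcr(y, X)
        assert res.total_r2 == pytest.approx(ols(y, X).r2, abs=1e-10)

    def test_scores_orthogonal_and_loadings_orthonormal(self, rng):
        n, p = 300, 4
        X = pd.DataFrame(rng.standard_normal((n, p)) @
                         (np.eye(p) + 0.4), columns=list("abcd"))
        res = pcr(rng.standard_normal(n), X)
        V = res.loadings.to_numpy()
        assert np.allclose(V.T @ V, np.eye(p), atol=1e-10)
        Z = (X - X.mean()) / X.std(ddof=1)
        scores = Z.to_numpy() @ V
        C = np.corrcoef(scores.T)
        assert np.allclose(C - np.diag(np.diag(C)), 0, atol=1e-10)

    def test_duplicate_column_degenerates_gracefully(self, rng):
        x = rng.standard_normal(100)
        X = pd.DataFrame({"x1": x, "x2": x, "z": rng.standard_normal(100)})
        y = x + rng.standard_normal(100)
        res = pcr(y, X)
        assert res.eigenvalues[-1] == pytest.approx(0.0, abs=1e-10)
        assert res.response_r2[-1] == 0.0
        assert res.total_r2 <= 1.0

    def test_sign_convention_largest_loading_positive(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
        res = pcr(rng.standard_normal(100), X)
        for k in range(3):
            col = res.loadings.iloc[:, k].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_constant_predictor_is_error(self, rng):
        X = pd.DataFrame({"x": np.ones(50), "y": rng.standard_normal(50)})
        with pytest.raises(ValueError, match="constant"):
            pcr(rng.standard_normal(50), X)


class TestChromosomeCovariateModel:
    def test_null_length_effect(self, rng):
        pi_a = rng.lognormal(-6, 0.3, 500)
        pi_b = 0.3 * pi_a + rng.normal(0, 1e-4, 500)
        length = rng.choice([5e6, 2e7, 8e7], 500)
        res = chromosome_covariate_model(pi_b, pi_a, length)
        assert abs(res.t("chrom_length")) < 3.5
        assert res.t("pi_other") > 10

    def test_recovers_injected_length_effect(self, rng):
        # additive chromosome-length effect recovered within 2 SE
        pi_a = rng.lognormal(-6, 0.3, 800)
        length = rng.choice([5e6, 2e7, 8e7], 800)
        slope = 1e-11
        pi_b = 0.3 * pi_a + slope * length + rng.normal(0, 2e-4, 800)
        res = chromosome_covariate_model(pi_b, pi_a, length)
        est, se = res.coef("chrom_length"), float(res.params.loc["chrom_length", "se"])
        assert abs(est - slope) < 2 * se
        assert res.p("chrom_length") < 0.05

    def test_too_few_windows_is_error(self):
        with pytest.raises(ValueError):
            chromosome_covariate_model([1e-3, 2e-3, 1e-3], [1e-3, 2e-3, 1e-3],
                                       [1e6, 2e6, 3e6])


class TestDecileRegression:
    def test_floor_rule_reproduces_df(self, rng):
        # 2 490 complete windows -> strata of 249 -> residual df 247
        n = 2490
        pi = rng.normal(3e-3, 3e-4, n)
        rec = rng.lognormal(0.7, 0.7, n)
        strat = rng.random(n)
        res = decile_stratified_regression(pi, rec, strat, "highest")
        assert res.n == 249
        assert res.df_resid == 247

    def test_strata_select_extremes(self, rng):
        n = 200
        strat = np.arange(n, dtype=float)
        pi = rng.normal(0, 1, n)
        rec = rng.normal(0, 1, n)
        lo = decile_stratified_regression(pi, rec, strat, "lowest")
        hi = decile_stratified_regression(pi, rec, strat, "highest")
        assert lo.n == hi.n == 20

    def test_constant_stratifier_is_error(self, rng):
        with pytest.raises(ValueError, match="constant"):
            decile_stratified_regression(rng.random(100), rng.random(100),
                                         np.ones(100), "highest")

    def test_interaction_detected_on_generator_truth(self):
        # linked-selection interaction: diversity responds to recombination
        # only where coding density is high
        rng = np.random.default_rng(99)
        n = 3000
        cds = rng.beta(0.55, 27.0, n)
        rec = rng.lognormal(np.log(2), 0.7, n)
        B = np.exp(-2.0 * cds / (rec + 0.1))
        pi = 0.004 * B * np.exp(rng.normal(0, 0.3, n))
        rec_t = np.log10(rec + 1)
        hi = decile_stratified_regression(pi, rec_t, cds, "highest")
        lo = decile_stratified_regression(pi, rec_t, cds, "lowest")
        assert hi.coef("rec") > lo.coef("rec")
        assert hi.p("rec") < 0.05
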