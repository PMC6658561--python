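"""Statistics suite: contingency, rank tests, ANOVA partitioning, the
normality gate and the permutation-of-regressor-residuals test.

Independent oracles: exhaustive expected-count evaluation and
scipy.stats.chi2_contingency for the 2x2 chi-square; scipy.stats.kruskal
for H; statsmodels OLS/anova_lm (Sum coding, typ=3) for the Type III
two-way table; explicit cell-mean formulas for the split-plot design.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stressprofiler.profiler import ContingencyTable2x2
from stressprofiler.stats import (
    dunn_pairwise,
    kruskal_wallis,
    mixed_three_way_anova,
    normality_gated_compare,
    pearson_correlation,
    permutation_regressor_residuals,
    sex_stratified_association,
    two_way_anova,
    yates_chi_square,
)


class TestYatesChiSquare:
    def test_printed_cohort_tables(self):
        r = yates_chi_square(ContingencyTable2x2(3, 32, 12, 34))
        assert round(r.statistic_corrected, 3) == 2.964
        assert round(r.phi, 3) == 0.223
        r = yates_chi_square(ContingencyTable2x2(6, 3, 1, 9))
        assert round(r.statistic_corrected, 3) == 4.328
        assert round(r.phi, 3) == 0.587

    def test_identical_proportions_clamp_to_zero(self):
        r = yates_chi_square(ContingencyTable2x2(10, 10, 10, 10))
        assert r.statistic_corrected == 0.0
        assert r.phi == 0.0
        assert r.p == 1.0

    def test_exhaustive_small_tables_vs_scipy(self):
        # every 2x2 with N <= 16 and positive marginals
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            r = yates_chi_square(np.array([[a, b], [c, d]]))
            chi2, p, df, _ = sps.chi2_contingency([[a, b], [c, d]], correction=True)
            assert r.statistic_corrected == pytest.approx(chi2, abs=1e-10)
            assert r.p == pytest.approx(p, abs=1e-10)
            chi2u, *_ = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert r.statistic_uncorrected == pytest.approx(chi2u, abs=1e-10)
            assert 0.0 <= r.phi <= 1.0

    def test_phi_one_iff_diagonal(self):
        assert yates_chi_square(np.array([[7, 0], [0, 5]])).phi == pytest.approx(1.0)
        assert yates_chi_square(np.array([[7, 1], [0, 5]])).phi < 1.0

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError, match="marginal"):
            yates_chi_square(np.array([[0, 0], [3, 4]]))


class TestKruskalWallis:
    def test_hand_computed_h(self):
        # ranks are the values themselves; H = 12/(N(N+1)) sum n R^2 - 3(N+1)
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9], [10, 11, 12]]
        r = kruskal_wallis(groups)
        assert round(r.H, 3) == 10.385
        assert r.df == 3
        assert r.mean_ranks == (2.0, 5.0, 8.0, 11.0)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(10):
            groups = [rng.integers(0, 6, size=rng.integers(4, 12)).astype(float)
                      for _ in range(3)]
            r = kruskal_wallis(groups)
            h, p = sps.kruskal(*groups)
            assert r.H == pytest.approx(h, abs=1e-10)
            assert r.p == pytest.approx(p, abs=1e-10)

    def test_weighted_mean_rank_identity(self, rng):
        groups = [rng.normal(size=n) for n in (5, 9, 14)]
        r = kruskal_wallis(groups)
        n_total = sum(r.group_sizes)
        weighted = sum(n * m for n, m in zip(r.group_sizes, r.mean_ranks)) / n_total
        assert weighted == pytest.approx((n_total + 1) / 2, abs=1e-10)

    def test_identical_groups_h_zero(self):
        r = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert r.H == pytest.approx(0.0, abs=1e-12)

    def test_all_values_identical_warns(self):
        with pytest.warns(RuntimeWarning):
            r = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert r.H == 0.0

    def test_rank_invariance_under_monotone_transform(self, rng):
        groups = [rng.normal(size=8) for _ in range(3)]
        r1 = kruskal_wallis(groups)
        r2 = kruskal_wallis([np.exp(g) for g in groups])
        assert r1.H == pytest.approx(r2.H, abs=1e-10)


class TestDunn:
    def test_two_group_z_squared_equals_h(self, rng):
        # algebraic identity: with 2 groups, Dunn z^2 == tie-corrected H
        for _ in range(5):
            groups = [rng.integers(0, 8, size=10).astype(float),
                      rng.integers(0, 8, size=7).astype(float)]
            d = dunn_pairwise(groups)
            h = kruskal_wallis(groups).H
            assert d.z[0] ** 2 == pytest.approx(h, abs=1e-9)

    def test_identical_groups_adjusted_p_one(self):
        d = dunn_pairwise([[1.0, 2.0, 3.0]] * 3)
        assert all(p == 1.0 for p in d.p_adjusted)

    def test_bonferroni_never_below_raw(self, rng):
        d = dunn_pairwise([rng.normal(size=6) for _ in range(4)])
        assert all(pa >= pr for pa, pr in zip(d.p_adjusted, d.p_raw))
        assert len(d.pairs) == 6

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            dunn_pairwise([[1.0, 2.0]])


def _balanced_2x2(cell_means, n=6, noise=0.0, seed=0):
    g = np.random.default_rng(seed)
    rows = []
    for (a, b), mu in cell_means.items():
        for _ in range(n):
            rows.append((a, b, mu + noise * g.normal()))
    df = pd.DataFrame(rows, columns=["a", "b", "y"])
    return df


class TestTwoWayAnova:
    def test_zero_noise_projection_oracle(self):
        # cells (10,10,10,20): direct least-squares on the effect-coded
        # design gives SS_A = SS_B = SS_AB = n*2.5^2... computed explicitly
        means = {("a1", "b1"): 10.0, ("a1", "b2"): 10.0,
                 ("a2", "b1"): 10.0, ("a2", "b2"): 20.0}
        n = 5
        df = _balanced_2x2(means, n=n)
        t = two_way_anova(df["y"], df["a"], df["b"])
        # oracle: balanced Type III == textbook factorial SS from cell means
        grand = np.mean(list(means.values()))
        a_means = {a: np.mean([m for (aa, _), m in means.items() if aa == a]) for a in ("a1", "a2")}
        b_means = {b: np.mean([m for (_, bb), m in means.items() if bb == b]) for b in ("b1", "b2")}
        ss_a = 2 * n * sum((v - grand) ** 2 for v in a_means.values())
        ss_b = 2 * n * sum((v - grand) ** 2 for v in b_means.values())
        ss_ab = n * sum(
            (means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
            for a in ("a1", "a2") for b in ("b1", "b2")
        )
        assert t["A"].ss == pytest.approx(ss_a, abs=1e-8)
        assert t["B"].ss == pytest.approx(ss_b, abs=1e-8)
        assert t["A:B"].ss == pytest.approx(ss_ab, abs=1e-8)
        assert t["residual"].ss == pytest.approx(0.0, abs=1e-8)

    def test_matches_statsmodels_type3_unbalanced(self):
        # unbalanced cells (n = 6-8): Type III with Sum (effect) coding
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        g = np.random.default_rng(42)
        rows = []
        for (a, b), n in {("a1", "b1"): 6, ("a1", "b2"): 8,
                          ("a2", "b1"): 7, ("a2", "b2"): 6}.items():
            mu = {"a1": 0.0, "a2": 1.0}[a] + {"b1": 0.0, "b2": 0.5}[b]
            rows += [(a, b, mu + g.normal()) for _ in range(n)]
        df = pd.DataFrame(rows, columns=["a", "b", "y"])
        t = two_way_anova(df["y"], df["a"], df["b"])
        fit = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
        ref = anova_lm(fit, typ=3)
        assert t["A"].ss == pytest.approx(ref.loc["C(a, Sum)", "sum_sq"], rel=1e-9)
        assert t["B"].ss == pytest.approx(ref.loc["C(b, Sum)", "sum_sq"], rel=1e-9)
        assert t["A:B"].ss == pytest.approx(
            ref.loc["C(a, Sum):C(b, Sum)", "sum_sq"], rel=1e-9
        )
        assert t["A"].p == pytest.approx(ref.loc["C(a, Sum)", "PR(>F)"], rel=1e-9)

    def test_pure_a_effect(self):
        means = {("a1", "b1"): 0.0, ("a1", "b2"): 0.0,
                 ("a2", "b1"): 3.0, ("a2", "b2"): 3.0}
        df = _balanced_2x2(means, n=8, noise=0.3, seed=7)
        t = two_way_anova(df["y"], df["a"], df["b"])
        assert t["A"].variance_explained > 0.8
        assert t["B"].variance_explained < 0.05
        assert t["A:B"].variance_explained < 0.05

    def test_eta_squared_sums_to_one_balanced(self):
        df = _balanced_2x2(
            {("a1", "b1"): 1.0, ("a1", "b2"): 2.0, ("a2", "b1"): 4.0, ("a2", "b2"): 3.0},
            n=6, noise=1.0, seed=3,
        )
        t = two_way_anova(df["y"], df["a"], df["b"])
        assert t.terms["variance_explained"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_shuffle_invariance(self):
        df = _balanced_2x2(
            {("a1", "b1"): 1.0, ("a1", "b2"): 2.0, ("a2", "b1"): 4.0, ("a2", "b2"): 3.0},
            n=6, noise=1.0, seed=3,
        )
        t1 = two_way_anova(df["y"], df["a"], df["b"])
        perm = np.random.default_rng(1).permutation(len(df))
        dfp = df.iloc[perm].reset_index(drop=True)
        t2 = two_way_anova(dfp["y"], dfp["a"], dfp["b"])
        pd.testing.assert_frame_equal(t1.terms, t2.terms, atol=1e-10)

    def test_empty_cell_errors(self):
        df = _balanced_2x2({("a1", "b1"): 1.0, ("a1", "b2"): 2.0, ("a2", "b1"): 3.0}, n=4)
        with pytest.raises(ValueError, match="2 levels|cell"):
            two_way_anova(df["y"], df["a"], df["b"])

    def test_posthoc_bonferroni_threshold(self):
        df = _balanced_2x2(
            {("a1", "b1"): 0.0, ("a1", "b2"): 0.0, ("a2", "b1"): 0.0, ("a2", "b2"): 5.0},
            n=6, noise=0.5, seed=11,
        )
        t = two_way_anova(df["y"], df["a"], df["b"])
        assert t.posthoc is not None and len(t.posthoc) == 6
        assert (t.posthoc["alpha_corrected"] == 0.05 / 4).all()


def _panel(cell_means_by_gene, n_per_cell=4, noise=0.0, seed=0):
    """Long-format split-plot panel: subjects nested in 2x2 cells, one
    observation per subject x gene."""
    g = np.random.default_rng(seed)
    rows = []
    sid = 0
    for (a, b) in [("c", "nt"), ("c", "t"), ("p", "nt"), ("p", "t")]:
        for _ in range(n_per_cell):
            subj = f"S{sid:03d}"
            sid += 1
            for gene, means in cell_means_by_gene.items():
                rows.append(
                    (subj, a, b, gene, means[(a, b)] + noise * g.normal())
                )
    return pd.DataFrame(rows, columns=["subject", "a", "b", "gene", "y"])


class TestSplitPlotAnova:
    GENES = {
        "g1": {("c", "nt"): 1.0, ("c", "t"): 0.7, ("p", "nt"): 0.8, ("p", "t"): 0.4},
        "g2": {("c", "nt"): 1.0, ("c", "t"): 1.0, ("p", "nt"): 1.0, ("p", "t"): 1.4},
        "g3": {("c", "nt"): 1.0, ("c", "t"): 0.9, ("p", "nt"): 1.0, ("p", "t"): 0.6},
        "g4": {("c", "nt"): 1.0, ("c", "t"): 1.0, ("p", "nt"): 1.1, ("p", "t"): 0.7},
    }

    def _fit(self, df):
        return mixed_three_way_anova(
            df, subject="subject", between_a="a", between_b="b",
            within="gene", value="y",
        )

    def test_zero_noise_cell_mean_oracle(self):
        # balanced, zero-noise: every SS reproducible from the enumerated
        # cell means by the classical factorial formulas
        n, g = 4, 4
        df = _panel(self.GENES, n_per_cell=n)
        t = self._fit(df)
        cm = df.groupby(["a", "b", "gene"])["y"].mean().unstack("gene")
        grand = df["y"].mean()
        a_m = df.groupby("a")["y"].mean()
        b_m = df.groupby("b")["y"].mean()
        ab_m = df.groupby(["a", "b"])["y"].mean()
        w_m = df.groupby("gene")["y"].mean()
        ss_a = n * 2 * g * ((a_m - grand) ** 2).sum()
        ss_b = n * 2 * g * ((b_m - grand) ** 2).sum()
        ss_ab = n * g * sum(
            (ab_m[a, b] - a_m[a] - b_m[b] + grand) ** 2
            for a in ("c", "p") for b in ("nt", "t")
        )
        ss_w = n * 4 * ((w_m - grand) ** 2).sum()
        assert t["a"].ss == pytest.approx(ss_a, abs=1e-8)
        assert t["b"].ss == pytest.approx(ss_b, abs=1e-8)
        assert t["a:b"].ss == pytest.approx(ss_ab, abs=1e-8)
        assert t["gene"].ss == pytest.approx(ss_w, abs=1e-8)
        # zero noise: both error strata vanish
        assert t["subject_error"].ss == pytest.approx(0.0, abs=1e-8)
        assert t["residual"].ss == pytest.approx(0.0, abs=1e-8)
        # and the decomposition is exhaustive
        assert t.terms["ss"].sum() == pytest.approx(t.ss_total, abs=1e-8)

    def test_within_effect_only(self):
        genes = {f"g{i}": {c: float(i) for c in
                           [("c", "nt"), ("c", "t"), ("p", "nt"), ("p", "t")]}
                 for i in range(1, 5)}
        df = _panel(genes, n_per_cell=3, noise=0.05, seed=2)
        t = self._fit(df)
        assert t["gene"].p < 1e-6
        for term in ("a", "b", "a:b"):
            assert t[term].ss == pytest.approx(0.0, abs=1.0)  # noise-level only

    def test_duplicating_subjects_doubles_ss(self):
        df = _panel(self.GENES, n_per_cell=3, noise=0.2, seed=5)
        dup = df.copy()
        dup["subject"] = dup["subject"] + "_dup"
        both = pd.concat([df, dup], ignore_index=True)
        t1, t2 = self._fit(df), self._fit(both)
        for term in ("a", "b", "a:b", "gene", "gene:a", "gene:b", "gene:a:b"):
            assert t2[term].ss == pytest.approx(2 * t1[term].ss, rel=1e-8)

    def test_incomplete_subject_excluded_with_warning(self):
        df = _panel(self.GENES, n_per_cell=3, noise=0.1, seed=8)
        df = df.drop(df[(df["subject"] == "S000") & (df["gene"] == "g1")].index)
        with pytest.warns(RuntimeWarning, match="excluded"):
            t = self._fit(df)
        # 11 complete subjects remain
        assert t["subject_error"].df == 11 - 4

    def test_unbalanced_between_cells(self):
        df = _panel(self.GENES, n_per_cell=4, noise=0.15, seed=9)
        df = df[df["subject"] != "S000"]  # 3/4/4/4 design
        t = self._fit(df)
        assert (t.terms.loc[["a", "b", "a:b", "gene"], "ss"] >= 0).all()
        assert t.terms["variance_explained"].sum() <= 1.0 + 1e-9


class TestNormalityGate:
    def test_normal_samples_take_t_route(self):
        # homoscedastic Normal samples dispatch to Student's t in most draws;
        # check the dominant route across seeds (each gate errs ~5% alone)
        routes = [
            normality_gated_compare(
                np.random.default_rng(s).normal(0, 1, 60),
                np.random.default_rng(s + 10_000).normal(0.2, 1, 60),
            ).route
            for s in range(20)
        ]
        assert routes.count("student_t") >= 15

    def test_heteroscedastic_normal_takes_welch(self, rng):
        x = rng.normal(0, 1, 80)
        y = rng.normal(0, 6, 80)
        rep = normality_gated_compare(x, y)
        assert rep.route in ("welch_t", "mann_whitney")
        if rep.route == "welch_t":
            assert rep.levene_p < 0.05

    def test_skewed_sample_takes_mann_whitney(self):
        # exponential at n = 30 fails Shapiro-Wilk with high probability;
        # check across seeds that the MW route dominates
        routes = []
        for s in range(20):
            g = np.random.default_rng(s)
            rep = normality_gated_compare(g.exponential(1, 30), g.normal(1, 1, 30))
            routes.append(rep.route)
        assert routes.count("mann_whitney") >= 15

    def test_identical_vectors(self, rng):
        x = rng.normal(size=30)
        rep = normality_gated_compare(x, x.copy())
        assert rep.p > 0.9
        assert rep.mean_difference == pytest.approx(0.0)

    def test_small_sample_errors(self):
        with pytest.raises(ValueError, match="n >= 3"):
            normality_gated_compare([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x + 3)[0] == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_coupled_pair_recovered_in_fisher_interval(self, rng):
        rho, n = -0.6, 200
        z = rng.normal(size=n)
        y = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)
        r, p, _ = pearson_correlation(z, y)
        half = 1.96 / np.sqrt(n - 3)
        lo, hi = np.tanh(np.arctanh(rho) - half), np.tanh(np.arctanh(rho) + half)
        assert lo <= r <= hi


class TestPermutationRegressorResiduals:
    def _null_data(self, seed, n=40):
        g = np.random.default_rng(seed)
        x = g.normal(size=(n, 2))
        reg = 0.5 * x[:, 0] + g.normal(size=n)  # correlated with covariates, not y
        y = x @ [1.0, -0.5] + g.normal(size=n)
        return y, x, reg

    def test_deterministic_given_seed(self):
        y, x, reg = self._null_data(0)
        r1 = permutation_regressor_residuals(y, x, reg, n_perm=99, seed=7)
        r2 = permutation_regressor_residuals(y, x, reg, n_perm=99, seed=7)
        assert r1.p_permutation == r2.p_permutation
        assert r1.F_observed == r2.F_observed

    def test_planted_effect_attains_minimal_p(self):
        g = np.random.default_rng(1)
        n = 50
        x = g.normal(size=(n, 2))
        reg = g.normal(size=n)
        y = x @ [0.3, 0.3] + 1.0 * reg + 0.1 * g.normal(size=n)
        r = permutation_regressor_residuals(y, x, reg, n_perm=999, seed=2)
        assert r.p_permutation == pytest.approx(1 / 1000)

    def test_affine_invariance_of_p(self):
        y, x, reg = self._null_data(3)
        r1 = permutation_regressor_residuals(y, x, reg, n_perm=199, seed=5)
        r2 = permutation_regressor_residuals(3.0 * y - 7.0, x, reg, n_perm=199, seed=5)
        assert r1.p_permutation == r2.p_permutation
        assert r1.F_observed == pytest.approx(r2.F_observed, rel=1e-9)

    def test_parametric_p_matches_ols_f(self):
        import statsmodels.api as sm

        y, x, reg = self._null_data(4)
        r = permutation_regressor_residuals(y, x, reg, n_perm=99, seed=0)
        full = sm.OLS(y, sm.add_constant(np.column_stack([x, reg]))).fit()
        assert r.p_parametric == pytest.approx(full.pvalues[-1], rel=1e-6)

    def test_constant_regressor_errors(self):
        y, x, _ = self._null_data(5)
        with pytest.raises(ValueError, match="constant"):
            permutation_regressor_residuals(y, x, np.ones_like(y), n_perm=99)

    def test_collinear_covariates_error(self):
        y, x, reg = self._null_data(6)
        xx = np.column_stack([x, x[:, 0]])
        with pytest.raises(ValueError, match="collinear"):
            permutation_regressor_residuals(y, xx, reg, n_perm=99)

    def test_too_few_permutations_error(self):
        y, x, reg = self._null_data(7)
        with pytest.raises(ValueError, match="99"):
            permutation_regressor_residuals(y, x, reg, n_perm=10)


class TestSexStratified:
    def test_male_only_slope_recovered(self):
        from stressprofiler.synthetic import HumanTableParams, simulate_human_table

        ht = simulate_human_table(HumanTableParams(seed=11, n_subjects=300,
                                                   sex_ratio=0.5))
        res = sex_stratified_association(ht, "expression", "tei").set_index("stratum")
        assert res.loc["M", "r"] < 0 and res.loc["M", "p"] < 0.05
        assert res.loc["F", "p"] > 0.05

    def test_identical_strata_identical_results(self, rng):
        n = 40
        base = pd.DataFrame({
            "y": rng.normal(size=n), "x": rng.normal(size=n), "sex": "M"})
        other = base.copy()
        other["sex"] = "F"
        res = sex_stratified_association(
            pd.concat([base, other], ignore_index=True), "y", "x")
        assert res.iloc[0]["r"] == pytest.approx(res.iloc[1]["r"])

    def test_small_stratum_skipped_with_warning(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(size=12), "x": rng.normal(size=12),
            "sex": ["M"] * 10 + ["F"] * 2})
        with pytest.warns(RuntimeWarning, match="skipped"):
            res = sex_stratified_association(df, "y", "x")
        assert list(res["stratum"]) == ["M"]

    def test_covariate_route_uses_permutation(self, rng):
        n = 60
        df = pd.DataFrame({
            "y": rng.normal(size=n), "x": rng.normal(size=n),
            "age": rng.normal(40, 10, size=n), "sex": ["M", "F"] * (n // 2)})
        res = sex_stratified_association(
            df, "y", "x", covariates=["age"], n_perm=99, seed=1)
        assert set(res["method"]) == {"perm_regressor_residuals"}
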