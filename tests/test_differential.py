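import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from planmet import (ValidationError, classify_overlap, differential_table,
                     filter_features, log10_transform, shapiro_wilk,
                     tukey_hsd, two_group_test, two_way_anova)
from planmet.differential import two_way_anova_matrix


def anova_oracle(values, f1, f2):
    """First-principles balanced two-factor decomposition from cell and
    marginal means (independent of the implementation under test)."""
    df = pd.DataFrame({"y": values, "a": f1, "b": f2})
    grand = df["y"].mean()
    ss_a = sum(len(g) * (g["y"].mean() - grand) ** 2
               for _, g in df.groupby("a"))
    ss_b = sum(len(g) * (g["y"].mean() - grand) ** 2
               for _, g in df.groupby("b"))
    ss_cells = sum(len(g) * (g["y"].mean() - grand) ** 2
                   for _, g in df.groupby(["a", "b"]))
    ss_tot = ((df["y"] - grand) ** 2).sum()
    return {"treatment": ss_a, "age": ss_b,
            "interaction": ss_cells - ss_a - ss_b,
            "residual": ss_tot - ss_cells}


class TestTwoWayAnova:
    def test_matches_first_principles_oracle(self, balanced_data):
        values, treatment, age = balanced_data
        res = two_way_anova(values, treatment, age)
        oracle = anova_oracle(values, treatment, age)
        for eff, ss in oracle.items():
            assert res[eff]["ss"] == pytest.approx(ss, rel=1e-9)

    def test_matches_statsmodels(self, balanced_data):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        values, treatment, age = balanced_data
        res = two_way_anova(values, treatment, age)
        frame = pd.DataFrame({"y": values, "t": treatment,
                              "a": pd.Categorical(age)})
        fit = ols("y ~ C(t) * C(a)", data=frame).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert res["treatment"]["F"] == pytest.approx(
            tab.loc["C(t)", "F"], rel=1e-9)
        assert res["interaction"]["p"] == pytest.approx(
            tab.loc["C(t):C(a)", "PR(>F)"], rel=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_ss_decomposition_sums_to_total(self, seed):
        rng = np.random.default_rng(seed)
        t = np.repeat(["c", "d"], 12)
        a = np.tile(np.repeat([1, 2, 3, 4], 3), 2)
        y = rng.normal(size=24) * rng.uniform(0.1, 10)
        res = two_way_anova(y, t, a)
        total = res.table.loc[["treatment", "age", "interaction",
                               "residual"], "ss"].sum()
        assert total == pytest.approx(((y - y.mean()) ** 2).sum(),
                                      rel=1e-9)

    def test_invariant_to_level_relabelling(self, balanced_data):
        values, treatment, age = balanced_data
        base = two_way_anova(values, treatment, age)
        relabeled = two_way_anova(
            values, np.where(treatment == "DA", "zzz", "aaa"),
            np.asarray(age) * 10 + 1)
        pd.testing.assert_frame_equal(base.table, relabeled.table)

    def test_single_level_factor_reduces_to_squared_t(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=12)
        t = np.repeat(["c", "d"], 6)
        res = two_way_anova(y, t, np.ones(12, dtype=int))
        tstat, _ = stats.ttest_ind(y[:6], y[6:], equal_var=True)
        assert res["treatment"]["F"] == pytest.approx(tstat ** 2, rel=1e-9)

    def test_unbalanced_design_is_hard_error(self):
        y = np.arange(11.0)
        t = ["c"] * 6 + ["d"] * 5
        a = [1, 1, 1, 2, 2, 2, 1, 1, 2, 2, 2]
        with pytest.raises(ValidationError, match="balanced"):
            two_way_anova(y, t, a)

    def test_zero_residual_df_rejected(self):
        with pytest.raises(ValidationError, match="residual"):
            two_way_anova([1.0, 2, 3, 4], ["c", "c", "d", "d"],
                          [1, 2, 1, 2])

    def test_null_type_one_error_in_band(self):
        rng = np.random.default_rng(2024)
        t = np.repeat(["c", "d"], 12)
        a = np.tile(np.repeat([1, 2, 3, 4], 3), 2)
        res = two_way_anova_matrix(rng.normal(size=(1000, 24)), t, a)
        for eff in ("treatment", "age", "interaction"):
            rate = (res[f"p_{eff}"] < 0.05).mean()
            lo, hi = stats.binom.interval(0.95, 1000, 0.05)
            assert lo / 1000 <= rate <= hi / 1000

    def test_recovery_on_full_design(self, full_design):
        """Interaction detection: sensitivity >= 0.9, FPR <= 0.07."""
        matrix, _sheet, _pw, truth = full_design
        logged = log10_transform(filter_features(matrix)[0])
        tp = fn = fp = tn = 0
        for genotype in ("EY05103", "Delta174"):
            table = differential_table(logged, genotype, alpha=0.05)
            for tissue, sub in table.groupby("tissue"):
                aff = truth.affected[(tissue, genotype)]
                hit = sub["metabolite"].isin(aff).to_numpy()
                sig = (sub["significant"] == 1).to_numpy()
                tp += (hit & sig).sum()
                fn += (hit & ~sig).sum()
                fp += (~hit & sig).sum()
                tn += (~hit & ~sig).sum()
        assert tp / (tp + fn) >= 0.9
        assert fp / (fp + tn) <= 0.07


class TestTukey:
    def test_identical_means_give_p_one(self):
        out = tukey_hsd([1.0, 1.0, 1.0], n_per_cell=3, ms_residual=2.0,
                        df_residual=6)
        np.testing.assert_allclose(out["p_adj"], 1.0, atol=1e-9)

    def test_k2_reduces_to_pairwise_t(self):
        """With two groups the studentized range collapses to |t|*sqrt(2),
        so the Tukey p equals the unadjusted two-sample p."""
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=6), rng.normal(1.0, 1, size=6)
        n, ms = 6, (a.var(ddof=1) + b.var(ddof=1)) / 2
        out = tukey_hsd([a.mean(), b.mean()], n_per_cell=n, ms_residual=ms,
                        df_residual=10)
        tstat = (a.mean() - b.mean()) / np.sqrt(2 * ms / n)
        p_t = 2 * stats.t.sf(abs(tstat), 10)
        assert out.loc[0, "p_adj"] == pytest.approx(p_t, abs=1e-6)

    def test_adjusted_at_least_unadjusted_for_k3(self):
        means = [0.0, 0.6, 1.5]
        n, ms, df = 4, 1.0, 9
        out = tukey_hsd(means, n_per_cell=n, ms_residual=ms, df_residual=df)
        for _, row in out.iterrows():
            t = abs(row["diff"]) / np.sqrt(2 * ms / n)
            p_unadj = 2 * stats.t.sf(t, df)
            assert row["p_adj"] >= p_unadj - 1e-12

    def test_bad_df_rejected(self):
        with pytest.raises(ValidationError):
            tukey_hsd([0.0, 1.0], 3, 1.0, 0)


class TestShapiroWilk:
    def test_published_reference_value(self):
        # classic 11-point weights sample; W from R 4.3 shapiro.test
        x = [148, 154, 158, 160, 161, 162, 166, 170, 182, 195, 236]
        w, p = shapiro_wilk(x)
        assert w == pytest.approx(0.7888146949, abs=1e-3)
        assert p == pytest.approx(0.0067, abs=1e-3)

    def test_w_at_most_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w, _ = shapiro_wilk(rng.normal(size=rng.integers(3, 40)))
            assert 0 < w <= 1

    def test_power_against_exponential(self):
        rng = np.random.default_rng(1)
        rejections = sum(shapiro_wilk(rng.exponential(size=50))[1] < 0.01
                         for _ in range(200))
        assert rejections / 200 >= 0.99

    @pytest.mark.parametrize("n", [2, 5001])
    def test_out_of_range_n_rejected(self, n):
        with pytest.raises(ValidationError):
            shapiro_wilk(np.ones(n))


class TestTwoGroupTest:
    def test_mann_whitney_exact_small_example(self):
        """{1,2} vs {3,4}: enumeration of all C(4,2) rank splits gives a
        two-sided p of 1/3, matching the package's exact branch."""
        from itertools import combinations
        from planmet.differential import _mann_whitney

        values = [1.0, 2.0, 3.0, 4.0]
        u_obs = _mann_whitney([1.0, 2.0], [3.0, 4.0])[0]
        # null distribution of U by brute-force enumeration
        us = []
        for pick in combinations(range(4), 2):
            a = [values[i] for i in pick]
            b = [values[i] for i in range(4) if i not in pick]
            us.append(sum(x > y for x in a for y in b))
        centre = np.mean(us)
        p_enum = np.mean([abs(u - centre) >= abs(u_obs - centre)
                          for u in us])
        assert p_enum == pytest.approx(1 / 3)
        assert _mann_whitney([1.0, 2.0], [3.0, 4.0])[1] == \
            pytest.approx(1 / 3)

    def test_all_tied_returns_one_with_flag(self):
        with pytest.warns(UserWarning, match="tied"):
            res = two_group_test([2.0, 2, 2], [2.0, 2, 2])
        assert res.p == 1.0 and res.all_tied

    def test_gaussian_data_uses_t(self):
        rng = np.random.default_rng(7)
        res = two_group_test(rng.normal(size=30), rng.normal(size=30))
        assert res.test == "t"

    def test_skewed_data_uses_mann_whitney(self):
        rng = np.random.default_rng(8)
        res = two_group_test(rng.exponential(size=40) ** 2,
                             rng.exponential(size=40) ** 2)
        assert res.test == "mannwhitney"

    def test_type_one_error_near_alpha(self):
        rng = np.random.default_rng(9)
        rej = sum(two_group_test(rng.normal(size=10),
                                 rng.normal(size=10)).p < 0.05
                  for _ in range(2000))
        lo, hi = stats.binom.interval(0.99, 2000, 0.05)
        assert lo <= rej <= hi

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValidationError):
            two_group_test([1.0, 2], [3.0, 4])


class TestClassification:
    @staticmethod
    def table(ps):
        return pd.DataFrame({
            "tissue": "brain", "metabolite": [f"m{i}" for i in range(len(ps))],
            "p_interaction": ps})

    def test_shared_and_exclusive_labels(self):
        out = classify_overlap(self.table([0.01, 0.01, 0.2, 0.2]),
                               self.table([0.01, 0.2, 0.01, 0.2]))
        assert out["classification"].tolist() == [
            "shared", "genotypeA_only", "genotypeB_only", "neither"]

    def test_mismatched_universe_reported(self):
        a = self.table([0.01, 0.2])
        b = self.table([0.01, 0.2, 0.5])
        with pytest.raises(ValidationError, match="m2"):
            classify_overlap(a, b)

    def test_overlap_fraction_recovered(self, full_design):
        """With overlap_fraction 0.5, the shared fraction among true
        positives lands in its 95% binomial band."""
        matrix, _sheet, _pw, truth = full_design
        logged = log10_transform(filter_features(matrix)[0])
        ta = differential_table(logged, "EY05103")
        tb = differential_table(logged, "Delta174")
        cls = classify_overlap(ta, tb)
        shared = hits = 0
        for tissue, sub in cls.groupby("tissue"):
            aff_a = truth.affected[(tissue, "EY05103")]
            aff_b = truth.affected[(tissue, "Delta174")]
            truly_shared = aff_a & aff_b
            sub = sub.set_index("metabolite")
            for m in truly_shared:
                hits += 1
                shared += sub.loc[m, "classification"] == "shared"
        # each truly shared metabolite must be detected in both genotypes
        rate = shared / hits
        power = 0.95 ** 2  # per-genotype sensitivity >= ~0.95
        lo, hi = stats.binom.interval(0.95, hits, power)
        assert lo / hits - 0.03 <= rate <= 1.0
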