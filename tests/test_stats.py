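"""Statistical pipeline: t-tests, ANOVAs, Holm-Sidak, decision cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from autoflux.flux_model import compute_estimates, turnover_ratios
from autoflux.stats import (
    InsufficientDataError,
    StatsValidationError,
    anova_one_way,
    anova_two_way,
    decision_pipeline,
    holm_sidak,
    t_one_sample_vs_one,
    t_two_sample,
    tier_label,
)
from conftest import make_design


def df2_t_cdf(t):
    """Closed-form Student-t CDF for 2 degrees of freedom."""
    return 0.5 + t / (2 * np.sqrt(2) * np.sqrt(1 + t**2 / 2))


class TestOneSampleVsOne:
    def test_worked_example_against_closed_form_cdf(self):
        res = t_one_sample_vs_one([1.2, 1.3, 1.1], "greater")
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == (2.0,)
        assert res.p_value == pytest.approx(1 - df2_t_cdf(3.4641016), abs=1e-6)
        assert res.p_value == pytest.approx(0.0371, abs=5e-4)
        assert res.tier == "significant"

    def test_mean_exactly_one_gives_p_half(self):
        res = t_one_sample_vs_one([0.9, 1.1], "greater")
        assert res.statistic == 0.0
        assert res.p_value == 0.5
        assert res.tier == "ns"

    def test_zero_variance_is_an_error(self):
        with pytest.raises(InsufficientDataError, match="variance"):
            t_one_sample_vs_one([1.0, 1.0, 1.0], "greater")

    def test_single_value_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            t_one_sample_vs_one([1.2], "greater")

    def test_less_direction_mirrors_greater(self):
        lo = t_one_sample_vs_one([0.8, 0.7, 0.9], "less")
        hi = t_one_sample_vs_one([1.2, 1.3, 1.1], "greater")
        assert lo.p_value == pytest.approx(hi.p_value, abs=1e-12)


class TestTwoSample:
    def test_identical_groups_give_p_half(self):
        res = t_two_sample([1, 2, 3], [1, 2, 3], "greater")
        assert res.statistic == 0.0 and res.p_value == 0.5

    def test_pooled_variance_hand_formula(self):
        a, b = [10, 11, 12], [13, 14, 15]
        res = t_two_sample(a, b, "greater")
        # textbook pooled-variance computation
        sa2 = np.var(a, ddof=1)
        sp = np.sqrt(((2) * sa2 + (2) * np.var(b, ddof=1)) / 4)
        t_hand = (np.mean(b) - np.mean(a)) / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.df == (4.0,)
        assert res.p_value == pytest.approx(sps.t.sf(t_hand, 4), rel=1e-12)

    def test_paired_equals_one_sample_on_differences(self):
        a, b = [10.0, 11.0, 12.5], [13.0, 14.5, 15.0]
        res = t_two_sample(a, b, "greater", paired=True)
        d = np.array(b) - np.array(a)
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.df == (2.0,)

    def test_translation_invariance(self):
        r1 = t_two_sample([1, 2, 3], [2, 4, 5], "greater")
        r2 = t_two_sample([101, 102, 103], [102, 104, 105], "greater")
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_paired_length_mismatch_raises(self):
        with pytest.raises(StatsValidationError, match="equal lengths"):
            t_two_sample([1, 2], [1, 2, 3], "greater", paired=True)

    def test_welch_flag_changes_df(self):
        res = t_two_sample([1, 2, 3], [10, 20, 35, 50], "greater", welch=True)
        assert res.test_name == "Welch t"
        assert res.df[0] != 5.0


class TestOneWayAnova:
    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=5), rng.normal(1, 2, size=7)
            tab = anova_one_way([a, b]).table
            t = sps.ttest_ind(a, b, equal_var=True)
            assert tab.loc["Between", "F"] == pytest.approx(t.statistic**2, rel=1e-8)
            assert tab.loc["Between", "p"] == pytest.approx(t.pvalue, rel=1e-8)

    def test_zero_within_variance_is_an_error(self):
        with pytest.raises(InsufficientDataError, match="within-group"):
            anova_one_way([[1, 1], [2, 2]])

    def test_empty_group_rejected(self):
        with pytest.raises(StatsValidationError, match="empty"):
            anova_one_way([[1, 2], []])

    def test_null_permutation_p_distribution_uniform(self):
        """Permuting labels of null data gives a uniform p distribution."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        ps = []
        for _ in range(2000):
            perm = rng.permutation(x)
            ps.append(anova_one_way([perm[:4], perm[4:8], perm[8:]]).table.loc["Between", "p"])
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.001


class TestTwoWayAnova:
    @staticmethod
    def _frame(values):
        rows = []
        for (c, i), vs in values.items():
            for v in vs:
                rows.append({"condition": c, "inhibitor": i, "value": v})
        return pd.DataFrame(rows)

    def test_additive_data_has_zero_interaction_ss(self):
        mu, alpha, beta = 10.0, {"a": 0, "b": 3}, {False: 0, True : 5}
        values = {
            (c, i): [mu + alpha[c] + beta[i] + e for e in (-1, 0, 1)]
            for c in alpha for i in beta
        }
        tab = anova_two_way(self._frame(values)).table
        assert tab.loc["condition:inhibitor", "sum_sq"] == pytest.approx(0, abs=1e-10)

    def test_matches_projection_matrix_least_squares(self):
        """F statistics agree with an explicit design-matrix computation."""
        rng = np.random.default_rng(8)
        values = {(c, i): list(rng.normal(size=4)) for c in ("a", "b") for i in (False, True)}
        df = self._frame(values)
        tab = anova_two_way(df).table

        # brute-force sequential SS via nested least-squares projections
        y = df["value"].to_numpy()
        a = (df["condition"] == "b").to_numpy(float)
        b = (df["inhibitor"]).to_numpy(float)
        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r
        one = np.ones_like(y)
        m0 = rss(np.c_[one])
        m1 = rss(np.c_[one, a])
        m2 = rss(np.c_[one, a, b])
        m3 = rss(np.c_[one, a, b, a * b])
        assert tab.loc["condition", "sum_sq"] == pytest.approx(m0 - m1, abs=1e-8)
        assert tab.loc["inhibitor", "sum_sq"] == pytest.approx(m1 - m2, abs=1e-8)
        assert tab.loc["condition:inhibitor", "sum_sq"] == pytest.approx(m2 - m3, abs=1e-8)
        assert tab.loc["Residual", "sum_sq"] == pytest.approx(m3, abs=1e-8)

    def test_ss_decomposition_sums_to_total(self):
        rng = np.random.default_rng(3)
        values = {(c, i): list(rng.normal(size=3)) for c in ("a", "b", "c") for i in (False, True)}
        df = self._frame(values)
        tab = anova_two_way(df).table
        total = ((df["value"] - df["value"].mean()) ** 2).sum()
        assert tab["sum_sq"].sum() == pytest.approx(total, rel=1e-8)

    def test_empty_cell_named_in_error(self):
        df = self._frame({("a", False): [1, 2], ("a", True): [2, 3], ("b", False): [1, 4]})
        with pytest.raises(StatsValidationError, match="empty design cell"):
            anova_two_way(df)


class TestHolmSidak:
    def test_single_p_is_identity(self):
        out = holm_sidak([0.03])
        assert out["p_adjusted"].iloc[0] == pytest.approx(0.03)
        assert bool(out["reject"].iloc[0])

    def test_hand_worked_two_p_example(self):
        out = holm_sidak([0.01, 0.04])
        assert out["p_adjusted"].tolist() == pytest.approx([1 - 0.99**2, 0.04])
        assert out["reject"].all()

    def test_step_down_stops_at_first_failure(self):
        out = holm_sidak([0.001, 0.2, 0.03])
        assert bool(out["reject"].iloc[0])
        assert not out["reject"].iloc[1]
        # 0.03 adjusted = 1-(1-.03)^2 = .0591 > .05 -> not rejected
        assert not out["reject"].iloc[2]

    def test_invalid_p_rejected(self):
        with pytest.raises(StatsValidationError):
            holm_sidak([0.5, 1.2])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_adjusted_ps_dominate_raw_and_are_monotone(self, ps):
        out = holm_sidak(ps)
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-15).all()
        srt = out.sort_values("p_raw", kind="stable")["p_adjusted"].to_numpy()
        assert np.all(np.diff(srt) >= -1e-15)
        assert (out["p_adjusted"] <= 1).all()

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        ps = [0.001, 0.008, 0.039, 0.041, 0.2, 0.6]
        ours = holm_sidak(ps)
        reject, adj, *_ = multipletests(ps, alpha=0.05, method="holm-sidak")
        np.testing.assert_allclose(ours["p_adjusted"], adj, rtol=1e-12)
        np.testing.assert_array_equal(ours["reject"], reject)


class TestTierLabels:
    @pytest.mark.parametrize(
        "p,tier", [(0.01, "significant"), (0.049, "significant"), (0.07, "tendency"),
                   (0.0999, "tendency"), (0.2, "ns"), (0.5, "ns")]
    )
    def test_thresholds(self, p, tier):
        assert tier_label(p) == tier


class TestTypeIError:
    def test_vs_one_test_rejection_rate_at_alpha(self):
        """Under null normal draws (mean 1, sd 0.1, n=3), the one-tailed
        vs-1 test rejects at alpha=0.05 within +-0.01 over 20,000 sims."""
        rng = np.random.default_rng(17)
        x = rng.normal(1.0, 0.1, size=(20000, 3))
        m = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1)
        t = (m - 1.0) / (sd / np.sqrt(3))
        p = sps.t.sf(t, 2)
        rate = float(np.mean(p < 0.05))
        assert abs(rate - 0.05) < 0.01
        # spot-check the vectorised oracle against the implementation
        res = t_one_sample_vs_one(x[0], "greater")
        assert res.p_value == pytest.approx(p[0], rel=1e-12)


class TestDecisionPipeline:
    @staticmethod
    def _run(design, **kw):
        est = compute_estimates(design)
        rat = turnover_ratios(est)
        return decision_pipeline(design.data, est.data, rat.data, **kw)

    def test_balanced_up_report_structure(self):
        d = make_design({("EXP-", False): 100, ("EXP-", True): 150,
                         ("EXP+", False): 100, ("EXP+", True): 200},
                        replicates=("R1", "R2", "R3"), noise=0.05, seed=0)
        rep = self._run(d)
        tiers = rep.all_tiers()
        assert "interaction" in tiers
        for q in ("flux", "formation", "degradation"):
            assert q in tiers
        for r in ("formation_ratio", "degradation_ratio", "net_ratio"):
            assert f"EXP+:{r}" in tiers
        assert all(t in ("significant", "tendency", "ns") for t in tiers.values())
        assert rep.screening["shapiro"] is not None

    def test_additive_data_skips_one_way_branch(self):
        # purely additive cell means + tiny noise: interaction should be ns
        d = make_design({("EXP-", False): 100, ("EXP-", True): 150,
                         ("EXP+", False): 120, ("EXP+", True): 170},
                        replicates=tuple(f"R{i}" for i in range(4)), noise=0.02, seed=6)
        rep = self._run(d)
        assert rep.interaction.tier == "ns"
        assert rep.one_way_by_inhibitor == {}
        assert any("skipped" in n for n in rep.notes)

    def test_interaction_triggers_one_way_within_inhibitor_levels(self):
        d = make_design({("EXP-", False): 100, ("EXP-", True): 150,
                         ("EXP+", False): 100, ("EXP+", True): 400},
                        replicates=("R1", "R2", "R3"), noise=0.02, seed=1)
        rep = self._run(d)
        assert rep.interaction.tier == "significant"
        assert set(rep.one_way_by_inhibitor) == {"BAF-", "BAF+"}

    def test_three_dose_design_takes_holm_sidak_branch(self):
        d = make_design({("EXP-", False): 100, ("EXP-", True): 150,
                         ("D1", False): 110, ("D1", True): 180,
                         ("D10", False): 120, ("D10", True): 260},
                        replicates=("R1", "R2", "R3"), noise=0.05, seed=2)
        rep = self._run(d)
        flux = rep.rate_tests["flux"]
        assert isinstance(flux, dict) and set(flux) == {"anova", "posthoc"}
        # vs-control: one comparison per treatment level
        assert len(flux["posthoc"]) == 2
        assert "tier" in flux["posthoc"].columns

    def test_directions_default_is_recorded(self):
        d = make_design({("EXP-", False): 100, ("EXP-", True): 150,
                         ("EXP+", False): 100, ("EXP+", True): 200},
                        replicates=("R1", "R2", "R3"), noise=0.05, seed=0)
        rep = self._run(d)
        assert any("defaulted" in n for n in rep.notes)
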