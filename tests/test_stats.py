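"""Group statistics: ANOVA + FDR, Bonferroni edge tests, Spearman and
demographics, with brute-force oracles for the multiple-testing step."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dmnaec.stats import (bonferroni_threshold, chi2_from_counts,
                          compare_cells, compare_edges, compare_demographics,
                          spearman_one_tailed, ttest_from_summary)
from statsmodels.stats.multitest import multipletests


def bh_stepup_oracle(pvals, alpha=0.05):
    """Benjamini-Hochberg by its step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= alpha * i / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def tidy_table(rng, n_per_group=10, effect=0.0, rois=("A", "B"),
               bands=("delta", "alpha")):
    rows = []
    for roi in rois:
        for band in bands:
            for g, shift in (("HC", 0.0), ("SCD", effect)):
                for k in range(n_per_group):
                    rows.append((f"{g}{k}", g, roi, band,
                                 rng.standard_normal() + shift))
    return pd.DataFrame(rows, columns=["subject", "group", "roi", "band",
                                       "strength"])


class TestCompareCells:
    def test_f_equals_t_squared(self, rng):
        table = tidy_table(rng, effect=1.0)
        out = compare_cells(table)
        cell = table.query("roi == 'A' and band == 'delta'")
        a = cell.query("group == 'HC'")["strength"]
        b = cell.query("group == 'SCD'")["strength"]
        t, p = sps.ttest_ind(a, b)
        row = out.query("roi == 'A' and band == 'delta'").iloc[0]
        assert row["F"] == pytest.approx(t**2, abs=1e-10)
        assert row["p"] == pytest.approx(p, abs=1e-12)

    def test_q_not_below_p_and_flags(self, rng):
        out = compare_cells(tidy_table(rng, effect=2.0))
        valid = out.dropna(subset=["p"])
        assert (valid["q"] >= valid["p"] - 1e-12).all()
        assert (valid["significant"] == (valid["q"] < 0.05)).all()

    def test_single_group_rejected(self, rng):
        table = tidy_table(rng)
        with pytest.raises(ValueError, match="2 groups"):
            compare_cells(table[table["group"] == "HC"])

    def test_worked_bh_example(self):
        # step-up on (0.001, 0.01, 0.02, 0.03, 0.5, 0.9) at alpha=.05
        p = [0.001, 0.01, 0.02, 0.03, 0.5, 0.9]
        assert bh_stepup_oracle(p).sum() == 4
        assert multipletests(p, method="fdr_bh")[0].sum() == 4

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([0.001, 0.004, 0.009, 0.02, 0.04,
                                     0.05, 0.2, 0.5, 0.9, 1.0]),
                    min_size=1, max_size=8))
    def test_bh_matches_stepup_oracle(self, pvals):
        ours = multipletests(pvals, alpha=0.05, method="fdr_bh")[0]
        assert np.array_equal(ours, bh_stepup_oracle(pvals, 0.05))


class TestCompareEdges:
    @staticmethod
    def edge_table(rng, effect=0.0, n=12):
        rows = []
        for band in ("delta",):
            for g, shift in (("HC", 0.0), ("SCD", effect)):
                for k in range(n):
                    rows.append((f"{g}{k}", g, "PCC_L", "LTC_R", band,
                                 rng.standard_normal() * 0.1 + 0.2 + shift))
        return pd.DataFrame(rows, columns=["subject", "group", "roi_i",
                                           "roi_j", "band", "aec"])

    def test_threshold_is_alpha_over_m(self):
        assert bonferroni_threshold(0.05, 11) == pytest.approx(0.0045, abs=5e-5)
        assert round(bonferroni_threshold(0.05, 11), 4) == 0.0045
        assert bonferroni_threshold(0.05, 1) == 0.05
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_effect_detected(self, rng):
        out = compare_edges(self.edge_table(rng, effect=0.4))
        assert bool(out["significant"].iloc[0])
        assert out["threshold"].iloc[0] == pytest.approx(0.05 / 11)

    def test_null_fwer_controlled(self, rng):
        # 1000 null replicates of 11 edges: family-wise error within the
        # binomial CI of the Bonferroni bound 1-(1-a/m)^m ~ 0.0488
        n0, n1, m, reps = 13, 14, 11, 1000
        a = rng.standard_normal((reps, m, n0))
        b = rng.standard_normal((reps, m, n1))
        p = sps.ttest_ind(a, b, axis=-1).pvalue
        fwer = (p < 0.05 / m).any(axis=1).mean()
        assert fwer <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        rho, p = spearman_one_tailed(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, p = spearman_one_tailed(x, -x)
        assert rho == pytest.approx(-1.0)
        assert p > 0.99

    def test_hand_ranked_example(self):
        # ranks differ by d = (1,1,1,1,0): rho = 1 - 6*4/120 = 0.8
        rho, _ = spearman_one_tailed([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_constant_input_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_one_tailed(np.ones(6), np.arange(6.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            spearman_one_tailed([1, 2, 3], [1, 2, 3])


class TestDemographics:
    def test_sex_counts_match_published_p(self):
        # 9/17 vs 9/18 males/females: chi-squared p ~ 0.92
        assert chi2_from_counts((9, 17), (9, 18)) == pytest.approx(0.92, abs=0.005)

    def test_education_summary_t(self):
        # 13.27+/-2.97 (n=26) vs 12.85+/-3.28 (n=27): p ~ 0.63
        p = ttest_from_summary(13.27, 2.97, 26, 12.85, 3.28, 27)
        assert p == pytest.approx(0.63, abs=0.005)

    def test_identical_numeric_columns_p_one(self, rng):
        x = rng.standard_normal(20)
        out = compare_demographics(numeric={"age": (x, x.copy())})
        assert out["p"].iloc[0] == 1.0

    def test_mixed_table_shape(self, rng):
        out = compare_demographics(
            numeric={"age": (rng.standard_normal(10) + 67,
                             rng.standard_normal(10) + 67)},
            categorical={"sex": ((9, 17), (9, 18))})
        assert list(out["kind"]) == ["numeric", "categorical"]
        assert ((0 <= out["p"]) & (out["p"] <= 1)).all()


class TestTypeICalibration:
    def test_permutation_rejection_rate_near_alpha(self, rng):
        # label permutations on one null cell: raw-p rejection rate ~ alpha
        n0, n1, reps, alpha = 13, 14, 1000, 0.05
        values = rng.standard_normal(n0 + n1)
        hits = 0
        for _ in range(reps):
            perm = rng.permutation(values)
            p = sps.f_oneway(perm[:n0], perm[n0:]).pvalue
            hits += p < alpha
        rate = hits / reps
        assert abs(rate - alpha) <= 3 * np.sqrt(alpha * (1 - alpha) / reps)
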