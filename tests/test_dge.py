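"""Normalization, interaction/ANOVA selection, BH, set overlap, ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dodderlign.dge import (
    CountMatrix,
    DGEThresholds,
    bh_adjust,
    cpm_normalize,
    deg_overlap,
    heatmap_order,
    interaction_dge,
    log2_cpm,
    twofactor_anova_dge,
)
from dodderlign.simulate.expression import simulate_counts

from conftest import four_cultivar_spec


def toy_matrix(values, genotypes=None, conditions=None):
    values = np.asarray(values)
    n = values.shape[1]
    samples = pd.DataFrame(
        {
            "genotype": genotypes or ["G1"] * n,
            "condition": conditions or ["infested"] * n,
            "replicate": range(1, n + 1),
        },
        index=[f"s{i}" for i in range(n)],
    )
    counts = pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples.index
    )
    return CountMatrix(counts, samples)


class TestCPM:
    def test_single_expressed_gene_takes_all(self):
        cm = toy_matrix([[10, 20], [0, 0]])
        cpm = cpm_normalize(cm)
        assert (cpm.iloc[0] == 1e6).all()

    def test_columns_sum_to_a_million(self, null_counts):
        sums = cpm_normalize(null_counts).sum(axis=0)
        assert np.allclose(sums, 1e6)

    def test_matches_hand_computation(self):
        cm = toy_matrix([[1, 4], [2, 5], [3, 6]])
        cpm = cpm_normalize(cm)
        expected = np.array([[1 / 6, 4 / 15], [2 / 6, 5 / 15], [3 / 6, 6 / 15]]) * 1e6
        assert np.allclose(cpm.values, expected)

    def test_zero_total_sample_named_in_error(self):
        cm = toy_matrix([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="s1"):
            cpm_normalize(cm)


class TestInteraction:
    def test_null_simulation_is_calibrated(self, null_counts):
        res = interaction_dge(null_counts, contrast=("H9553", "H9775"))
        assert (res["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_planted_effects_detected_with_power(self, planted_counts):
        cm, truth = planted_counts
        res = interaction_dge(cm, contrast=("H9553", "H9775"))
        assert res["passes"][truth.cluster_labels == 1].mean() >= 0.9

    def test_default_thresholds_are_published_values(self):
        t = DGEThresholds()
        assert (t.fdr_max, t.log2fc_min, t.fc_min) == (0.1, 1.0, 1.5)

    def test_log2fc_is_difference_of_differences(self, planted_counts):
        cm, truth = planted_counts
        res = interaction_dge(cm, contrast=("H9553", "H9775"))
        lc = log2_cpm(cm)
        strata = cm.strata()

        def stratum_mean(gene, s):
            return lc.loc[gene, strata.index[strata == s]].mean()

        gene = truth.cluster_labels.index[truth.cluster_labels == 1][0]
        expected = (
            stratum_mean(gene, ("H9553", "infested"))
            - stratum_mean(gene, ("H9553", "uninfested"))
        ) - (
            stratum_mean(gene, ("H9775", "infested"))
            - stratum_mean(gene, ("H9775", "uninfested"))
        )
        assert res.loc[gene, "log2fc"] == pytest.approx(expected, abs=1e-9)

    def test_matches_statsmodels_ols(self):
        """Cross-check p-values against an independent statsmodels fit."""
        import statsmodels.formula.api as smf

        cm, _ = simulate_counts(four_cultivar_spec(n_genes=5, seed=33))
        res = interaction_dge(cm, contrast=("H9553", "H1706"))
        lc = log2_cpm(cm)
        for gene in cm.counts.index:
            df = cm.samples.copy()
            df["y"] = lc.loc[gene, df.index].values
            fit = smf.ols("y ~ C(condition) * C(genotype)", data=df).fit()
            name = (
                "C(condition)[T.uninfested]:C(genotype)[T.H9553]"
            )
            # same contrast up to sign (uninfested is the non-reference level)
            assert res.loc[gene, "p"] == pytest.approx(fit.pvalues[name], rel=1e-6)

    def test_unreplicated_stratum_rejected(self):
        cm = toy_matrix(
            [[1, 2, 3, 4]],
            genotypes=["G1", "G1", "G1", "G2"],
            conditions=["infested", "infested", "uninfested", "infested"],
        )
        with pytest.raises(ValueError, match="replicate"):
            interaction_dge(cm)


class TestAnova:
    @staticmethod
    def oneway_f(groups):
        """Textbook one-way ANOVA F from sums of squares."""
        all_vals = np.concatenate(groups)
        grand = all_vals.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        df1 = len(groups) - 1
        df2 = len(all_vals) - len(groups)
        return (ssb / df1) / (ssw / df2)

    def test_oneway_oracle_reproduces_textbook_value(self):
        """Sanity-check the oracle itself: {1,2,3} vs {4,5,6} -> F = 13.5."""
        assert self.oneway_f([[1, 2, 3], [4, 5, 6]]) == pytest.approx(13.5)

    def test_degenerate_single_factor_equals_closed_form_oneway(self):
        """With one factor constant, the omnibus F reduces to one-way ANOVA."""
        rng = np.random.default_rng(17)
        counts = rng.integers(50, 2000, size=(10, 6))
        cm = toy_matrix(
            counts, genotypes=["G1"] * 3 + ["G2"] * 3, conditions=["infested"] * 6
        )
        res = twofactor_anova_dge(cm)
        lc = log2_cpm(cm)
        for gene in lc.index:
            expected = self.oneway_f([lc.loc[gene][:3], lc.loc[gene][3:]])
            assert res.loc[gene, "F"] == pytest.approx(expected)

    def test_anova_f_equals_scipy_oneway(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(7)
        counts = rng.integers(50, 2000, size=(20, 6))
        cm = toy_matrix(
            counts, genotypes=["G1"] * 3 + ["G2"] * 3, conditions=["infested"] * 6
        )
        res = twofactor_anova_dge(cm)
        lc = log2_cpm(cm)
        for gene in lc.index:
            F, p = f_oneway(lc.loc[gene][:3], lc.loc[gene][3:])
            assert res.loc[gene, "F"] == pytest.approx(F)
            assert res.loc[gene, "p"] == pytest.approx(p)

    def test_identical_strata_give_empty_deg_set(self):
        counts = np.tile([[100], [200]], (1, 8))
        cm = toy_matrix(
            counts,
            genotypes=["G1", "G1", "G2", "G2"] * 2,
            conditions=["infested"] * 4 + ["uninfested"] * 4,
        )
        res = twofactor_anova_dge(cm)
        assert not res["passes"].any()

    def test_planted_effects_detected(self, planted_counts):
        cm, truth = planted_counts
        res = twofactor_anova_dge(cm)
        assert res["passes"][truth.cluster_labels == 1].mean() >= 0.9


class TestBH:
    def test_worked_four_pvalue_example(self):
        """Step-up: p=(.01,.02,.03,.04), m=4 -> all adjusted to .04."""
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_stepup_definition_on_random_pvalues(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=37)
        adj = bh_adjust(p)
        order = np.argsort(p)
        m = len(p)
        # independent step-up evaluation
        expected_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(expected_sorted, 1.0)
        assert np.allclose(adj, expected)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_adjusted_at_least_raw_and_capped(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_stricter_fdr_gives_subset(self, null_counts):
        res = twofactor_anova_dge(null_counts)
        strict = set(res.index[res["fdr"] < 0.05])
        loose = set(res.index[res["fdr"] < 0.1])
        assert strict <= loose


class TestOverlap:
    def test_disjoint_sets(self):
        regions = deg_overlap({"a": {1, 2, 3}, "b": {4, 5, 6, 7, 8}})
        assert regions[frozenset({"a", "b"})] == 0
        assert regions[frozenset({"a"})] == 3
        assert regions[frozenset({"b"})] == 5

    def test_identical_sets(self):
        regions = deg_overlap({"a": {1, 2}, "b": {1, 2}})
        assert regions[frozenset({"a", "b"})] == 2
        assert regions[frozenset({"a"})] == 0

    def test_four_random_sets_match_membership_enumeration(self):
        rng = np.random.default_rng(5)
        sets = {
            label: set(rng.choice(100, size=rng.integers(10, 60), replace=False))
            for label in "abcd"
        }
        regions = deg_overlap(sets)
        # brute force: classify each element of the universe by membership tuple
        expected: dict[frozenset, int] = {k: 0 for k in regions}
        for x in range(100):
            member = frozenset(l for l, s in sets.items() if x in s)
            if member:
                expected[member] += 1
        assert regions == expected
        assert sum(regions.values()) == len(set.union(*sets.values()))


class TestHeatmapOrder:
    def test_identical_rows_adjacent(self):
        rows, _ = heatmap_order(np.array([[1.0, 2.0], [9.0, 9.0], [1.0, 2.0]]))
        pos = {r: i for i, r in enumerate(rows)}
        assert abs(pos[0] - pos[2]) == 1

    def test_one_dimensional_toy_pairs(self):
        rows, _ = heatmap_order(np.array([[0.0], [1.0], [10.0], [11.0]]))
        pos = {r: i for i, r in enumerate(rows)}
        assert abs(pos[0] - pos[1]) == 1
        assert abs(pos[2] - pos[3]) == 1

    def test_leaf_order_is_permutation(self, null_counts):
        sub = log2_cpm(null_counts).iloc[:30]
        rows, cols = heatmap_order(sub)
        assert sorted(rows) == list(range(30))
        assert sorted(cols) == list(range(sub.shape[1]))

    def test_single_row_identity(self):
        rows, _ = heatmap_order(np.array([[1.0, 2.0]]))
        assert list(rows) == [0]
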