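"""Statistical layer: omnibus tests, post hoc, assumption gates.

Independent oracles: the Friedman statistic is recomputed from the raw
rank formula with tie correction, and the mixed-design ANOVA from a naive
sums-of-squares decomposition; both are compared against the package's
implementations.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cogload.stats import (
    assumption_gates,
    friedman,
    mixed_rm_anova,
    omnibus_across_tasks,
    posthoc_pairwise,
    rm_anova,
)


def naive_friedman(mat):
    """Rank-formula oracle with tie correction."""
    n, k = mat.shape
    ranks = np.vstack([sps.rankdata(row) for row in mat])
    rj = ranks.sum(axis=0)
    chi = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in mat:
        _vals, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    correction = 1.0 - ties / (n * (k**3 - k))
    chi /= correction
    return chi, sps.chi2.sf(chi, k - 1)


def naive_split_plot_anova(values, groups):
    """Direct sums-of-squares oracle for a balanced 2-between x k-within
    design.  ``values``: subjects x conditions; ``groups``: label per subject."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n, k = values.shape
    grand = values.mean()
    glabels = np.unique(groups)

    subj_means = values.mean(axis=1)
    group_means = {g: values[groups == g].mean() for g in glabels}
    cond_means = values.mean(axis=0)

    ss_group = k * sum(
        (groups == g).sum() * (group_means[g] - grand) ** 2 for g in glabels
    )
    ss_subj_w = k * sum(
        (subj_means[i] - group_means[groups[i]]) ** 2 for i in range(n)
    )
    ss_task = n * np.sum((cond_means - grand) ** 2)
    ss_inter = 0.0
    for g in glabels:
        sel = values[groups == g]
        ng = sel.shape[0]
        for j in range(k):
            ss_inter += ng * (
                sel[:, j].mean() - group_means[g] - cond_means[j] + grand
            ) ** 2
    ss_total = np.sum((values - grand) ** 2)
    ss_err = ss_total - ss_group - ss_subj_w - ss_task - ss_inter

    df_group, df_subj = len(glabels) - 1, n - len(glabels)
    df_task = k - 1
    df_inter = df_group * df_task
    df_err = df_subj * df_task
    out = {}
    out["group"] = dict(
        F=(ss_group / df_group) / (ss_subj_w / df_subj),
        np2=ss_group / (ss_group + ss_subj_w),
        df=(df_group, df_subj),
    )
    out["task"] = dict(
        F=(ss_task / df_task) / (ss_err / df_err),
        np2=ss_task / (ss_task + ss_err),
        df=(df_task, df_err),
    )
    out["Interaction"] = dict(
        F=(ss_inter / df_inter) / (ss_err / df_err),
        np2=ss_inter / (ss_inter + ss_err),
        df=(df_inter, df_err),
    )
    for v in out.values():
        v["p"] = sps.f.sf(v["F"], *v["df"])
    return out


def long_format(values, groups):
    n, k = values.shape
    rows = []
    for i in range(n):
        for j in range(k):
            rows.append(dict(participant=f"s{i}", group=groups[i],
                             task=f"t{j}", value=values[i, j]))
    return pd.DataFrame(rows)


class TestFriedman:
    def test_concordant_rankings_closed_form(self):
        # 3 raters, 3 conditions, perfect agreement: chi2 = 6, p = exp(-3)
        mat = np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0], [2.0, 4.0, 8.0]])
        res = friedman(mat)
        assert res.statistic == pytest.approx(6.0)
        assert res.p_value == pytest.approx(np.exp(-3.0), rel=1e-6)
        assert res.effect_size == pytest.approx(1.0)  # Kendall's W

    def test_identical_columns_null(self):
        mat = np.tile([[1.0, 1.0, 1.0, 1.0]], (6, 1))
        res = friedman(mat)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_no_effect_low_statistic(self, rng):
        mat = rng.normal(size=(12, 4))
        res = friedman(mat)
        assert res.p_value > 0.001  # null data should rarely be extreme

    def test_matches_rank_formula_oracle(self, rng):
        for _ in range(60):
            mat = rng.normal(size=(8, 4))
            res = friedman(mat)
            chi, p = naive_friedman(mat)
            assert res.statistic == pytest.approx(chi, abs=1e-9)
            assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_missing_cells_rejected(self):
        mat = np.array([[1.0, 2.0, 3.0], [4.0, np.nan, 6.0]])
        with pytest.raises(ValueError):
            friedman(mat)


class TestPosthoc:
    def test_pair_count(self, rng):
        mat = rng.normal(size=(10, 4))
        assert len(posthoc_pairwise(mat)) == 6

    def test_bonferroni_cap_and_monotonicity(self, rng):
        mat = rng.normal(size=(10, 4))
        ph = posthoc_pairwise(mat)
        raws = [p["p_raw"] for p in ph]
        adjs = [p["p_adjusted"] for p in ph]
        for r, a in zip(raws, adjs):
            assert a >= r
            assert a <= 1.0
            assert a == pytest.approx(min(1.0, r * 6))
        order = np.argsort(raws)
        assert np.all(np.diff(np.array(adjs)[order]) >= -1e-12)

    def test_degenerate_pair_flagged(self):
        mat = np.column_stack([np.arange(8.0)] * 2 + [np.arange(8.0) + 1])
        ph = posthoc_pairwise(mat)
        flags = {p["pair"]: p["degenerate"] for p in ph}
        assert flags[("0", "1")] is True
        assert flags[("0", "2")] is False

    def test_shifted_condition_dominates_significant_pairs(self, rng):
        # one condition moved by +1 SD: at n=25 its pairs should carry the signal
        mat = rng.normal(size=(25, 4))
        mat[:, 2] += 1.0
        ph = posthoc_pairwise(mat)
        sig = [p["pair"] for p in ph if p["significant"]]
        assert sig, "expected significant pairs with a 1 SD shift at n=25"
        assert all("2" in pair for pair in sig)


class TestMixedANOVA:
    def test_matches_naive_ss_oracle(self, rng):
        for _ in range(10):
            values = rng.normal(size=(6, 4))
            groups = np.array(["A"] * 3 + ["B"] * 3)
            res = mixed_rm_anova(long_format(values, groups))
            oracle = naive_split_plot_anova(values, groups)
            got = {r["source"]: r for r in res.table}
            for src in ("group", "task", "Interaction"):
                assert got[src]["F"] == pytest.approx(oracle[src]["F"], abs=1e-8)
                assert got[src]["partial_eta_sq"] == pytest.approx(
                    oracle[src]["np2"], abs=1e-8
                )

    def test_null_between_factor(self, rng):
        # group B is an exact copy of group A: group effect vanishes
        half = rng.normal(size=(4, 4))
        values = np.vstack([half, half])
        groups = np.array(["A"] * 4 + ["B"] * 4)
        res = mixed_rm_anova(long_format(values, groups))
        grp = next(r for r in res.table if r["source"] == "group")
        assert grp["F"] == pytest.approx(0.0, abs=1e-10)
        assert grp["p"] == pytest.approx(1.0, abs=1e-10)

    def test_large_task_effect_dominates(self, rng):
        values = rng.normal(size=(10, 4), scale=0.5)
        values += np.array([0.0, 1.0, 2.0, 3.0])  # strong within effect
        groups = np.array(["A"] * 5 + ["B"] * 5)
        res = mixed_rm_anova(long_format(values, groups))
        got = {r["source"]: r for r in res.table}
        assert got["task"]["partial_eta_sq"] > got["group"]["partial_eta_sq"]
        assert res.p_value < 0.001

    def test_unbalanced_groups_supported(self, rng):
        values = rng.normal(size=(7, 4))
        groups = np.array(["A"] * 3 + ["B"] * 4)
        res = mixed_rm_anova(long_format(values, groups))
        oracle = naive_split_plot_anova(values, groups)
        got = {r["source"]: r for r in res.table}
        assert got["task"]["F"] == pytest.approx(oracle["task"]["F"], abs=1e-8)


class TestGates:
    def test_gaussian_type_I_rate(self, rng):
        rejects = sum(
            sps.shapiro(rng.normal(size=25)).pvalue < 0.05 for _ in range(500)
        )
        assert 0.02 <= rejects / 500 <= 0.09

    def test_heavy_tails_detected(self, rng):
        rejects = sum(
            sps.shapiro(rng.standard_t(df=2, size=25)).pvalue < 0.05
            for _ in range(200)
        )
        assert rejects / 200 > 0.3

    def test_levene_calibrated_on_equal_variances(self, rng):
        rejects = sum(
            sps.levene(rng.normal(size=25), rng.normal(size=25)).pvalue < 0.05
            for _ in range(500)
        )
        assert 0.02 <= rejects / 500 <= 0.09

    def test_gate_mapping_keys(self, rng):
        mat = rng.normal(size=(20, 4))
        gates = assumption_gates(mat)
        assert set(gates) == {"normality_p", "variance_homogeneity_p", "sphericity_p"}
        assert all(0 <= v <= 1 for v in gates.values())

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError):
            assumption_gates(rng.normal(size=(2, 4)))


class TestOmnibusRouting:
    def test_gaussian_data_routes_to_anova(self, rng):
        wide = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        # normality can still randomly fail; use data passing the gate
        while assumption_gates(wide)["normality_p"] < 0.05:
            wide = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        res = omnibus_across_tasks(wide)
        assert res.test.startswith("rm_anova")
        assert "mean" in next(iter(res.descriptives["per_condition"].values()))

    def test_skewed_data_routes_to_friedman(self, rng):
        wide = pd.DataFrame(rng.lognormal(0, 1.5, size=(25, 4)), columns=list("abcd"))
        res = omnibus_across_tasks(wide)
        assert res.test == "friedman"
        assert "median" in next(iter(res.descriptives["per_condition"].values()))

    def test_rm_anova_matches_naive_one_way_ss(self, rng):
        values = rng.normal(size=(6, 4))
        res = rm_anova(pd.DataFrame(values))
        n, k = values.shape
        grand = values.mean()
        ss_cond = n * np.sum((values.mean(axis=0) - grand) ** 2)
        ss_subj = k * np.sum((values.mean(axis=1) - grand) ** 2)
        ss_err = np.sum((values - grand) ** 2) - ss_cond - ss_subj
        f = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        assert res.statistic == pytest.approx(f, abs=1e-8)
        assert res.effect_size == pytest.approx(ss_cond / (ss_cond + ss_err), abs=1e-8)
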