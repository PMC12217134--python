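"""Rank-based tests, ART factorial analysis, ICC, and Bland-Altman,
cross-checked against enumeration/permutation oracles and analytic
variance-component targets."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import rodentmorph as rm
from rodentmorph.stats import align_for_effect
from rodentmorph.types import DesignError


# ---------------------------------------------------------------------------
# independent oracles


def _kw_statistic(groups):
    """Tie-corrected Kruskal-Wallis H computed from first principles."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


def _kw_permutation_p(groups, n_perm=100_000, seed=123):
    """Monte-Carlo permutation null of the KW statistic on the same data."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    observed = _kw_statistic(groups)
    rng = np.random.default_rng(seed)
    count = 0
    edges = np.cumsum([0] + sizes)
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        shuffled = [perm[edges[i] : edges[i + 1]] for i in range(len(sizes))]
        if _kw_statistic(shuffled) >= observed - 1e-12:
            count += 1
    return count / n_perm


def _ranksum_exact_p(x, y):
    """Exhaustive two-sided rank-sum p over all C(n+m, n) assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2.0
    stats = [
        abs(sum(ranks[list(idx)]) - mu)
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    return float(np.mean(np.asarray(stats) >= abs(obs - mu) - 1e-12))


# ---------------------------------------------------------------------------


class TestKruskalWallis:
    def test_no_variation(self):
        r = rm.kruskal_wallis([[7, 7], [7, 7], [7, 7], [7, 7]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0
        assert r.df == 3

    def test_matches_permutation_oracle(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        r = rm.kruskal_wallis(groups)
        p_perm = _kw_permutation_p(groups)
        # at this n the implementation enumerates the exact null, so it
        # must sit within Monte-Carlo error of the shuffled oracle
        se = 3 * np.sqrt(p_perm * (1 - p_perm) / 100_000 + 1e-9)
        assert r.p_value == pytest.approx(p_perm, abs=max(0.005, se))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_two_groups_match_rank_sum(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 1, 12)
        kw = rm.kruskal_wallis([x, y])
        rs = rm.rank_sum(x, y)
        assert kw.p_value == pytest.approx(rs.p_value, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rm.kruskal_wallis([[1, 2], []])


class TestRankSum:
    def test_extreme_arrangement_exact(self):
        r = rm.rank_sum([1, 2, 3], [10, 20, 30])
        assert r.p_value == pytest.approx(0.1, abs=1e-12)
        assert r.p_value == pytest.approx(_ranksum_exact_p([1, 2, 3], [10, 20, 30]))

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 4)
        y = rng.normal(0.8, 1, 5)
        r = rm.rank_sum(x, y)
        assert r.p_value == pytest.approx(_ranksum_exact_p(x, y), abs=1e-9)

    def test_identical_paired(self):
        r = rm.rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert r.p_value == 1.0

    def test_shift_detected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 20)
        y = rng.normal(2, 1, 20)
        assert rm.rank_sum(x, y).p_value < 0.05

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            rm.rank_sum([1, 2, 3], [1, 2], paired=True)


class TestBonferroni:
    def test_scaling(self):
        assert rm.adjust_bonferroni([0.01, 0.02, 0.03, 0.04, 0.05]) == pytest.approx(
            [0.05, 0.10, 0.15, 0.20, 0.25]
        )

    def test_cap(self):
        assert rm.adjust_bonferroni([0.5, 0.5, 0.5]) == [1.0, 1.0, 1.0]

    def test_singleton(self):
        assert rm.adjust_bonferroni([0.37]) == [0.37]

    def test_monotone_order_preserving(self, rng):
        ps = sorted(rng.uniform(0, 1, 8))
        adj = rm.adjust_bonferroni(ps)
        assert all(a >= p for a, p in zip(adj, ps))
        assert adj == sorted(adj)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            rm.adjust_bonferroni([0.5, 1.2])


class TestPosthoc:
    @pytest.mark.parametrize("method", ["tukey_on_ranks", "rank_sum"])
    def test_identical_groups(self, method):
        groups = [[3.0, 3.0, 3.0, 3.0]] * 3
        results = rm.posthoc_pairwise(groups, method=method)
        assert all(r.p_adjusted == 1.0 for r in results)

    @pytest.mark.parametrize("method", ["tukey_on_ranks", "rank_sum"])
    def test_separated_groups(self, method):
        groups = [[1, 2, 3, 4, 5], [101, 102, 103, 104, 105], [201, 202, 203, 204, 205]]
        results = rm.posthoc_pairwise(groups, method=method)
        assert all(r.p_adjusted < 0.05 for r in results)

    def test_comparison_count(self):
        groups = [np.arange(5) + 10 * k for k in range(4)]
        assert len(rm.posthoc_pairwise(groups)) == 6

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 6) for m in (0, 0.5, 1.0)]
        for r in rm.posthoc_pairwise(groups, method="rank_sum"):
            assert r.p_adjusted >= r.p_value


class TestArtAnova:
    @staticmethod
    def _layout(n_rep=5):
        a = np.repeat(["a1", "a2"], 2 * n_rep)
        b = np.tile(np.repeat(["b1", "b2"], n_rep), 2)
        return a, b

    def test_no_variation(self):
        a, b = self._layout()
        res = rm.art_anova_2way(np.zeros(len(a)), a, b)
        assert all(r.statistic == 0.0 and r.p_value == 1.0 for r in res.values())

    def test_pure_main_effect(self):
        rng = np.random.default_rng(42)
        a, b = self._layout()
        detected_a, inflated_inter = 0, 0
        for _ in range(40):
            y = (a == "a2") * 3.0 + rng.normal(0, 1, len(a))
            res = rm.art_anova_2way(y, a, b)
            if res["A"].p_value < 0.01:
                detected_a += 1
            if res["A:B"].p_value < 0.1:
                inflated_inter += 1
        assert detected_a >= 38  # strong main effect nearly always found
        assert inflated_inter <= 10  # interaction stays near its null rate

    def test_interaction_power(self):
        rng = np.random.default_rng(7)
        a = np.repeat(["a1", "a2"], 15)
        b = np.tile(np.repeat(["b1", "b2", "b3"], 5), 2)
        hits = 0
        n_sim = 60
        # pure interaction pattern (zero marginal means): +/- 2 SD cell
        # contrast between the extreme factor-B levels, reversed across A
        contrast = {"b1": -1.0, "b2": 0.0, "b3": 1.0}
        sign = np.where(a == "a2", 1.0, -1.0)
        pattern = sign * np.array([contrast[x] for x in b])
        for _ in range(n_sim):
            y = rng.normal(0, 1, len(a)) + 1.0 * pattern
            res = rm.art_anova_2way(y, a, b)
            if res["A:B"].p_value < 0.05:
                hits += 1
        assert hits / n_sim >= 0.8

    def test_alignment_zeroes_other_effects(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        a, b = self._layout()
        y = (
            rng.normal(0, 1, len(a))
            + 2.0 * (a == "a2")
            + 1.5 * (b == "b2")
            + 1.0 * ((a == "a2") & (b == "b2"))
        )
        term = {"a": "C(a)", "b": "C(b)", "a:b": "C(a):C(b)"}
        for effect in ("a", "b", "a:b"):
            aligned = align_for_effect(y, a, b, effect)
            fit = smf.ols(
                "v ~ C(a) * C(b)", data=pd.DataFrame({"v": aligned, "a": a, "b": b})
            ).fit()
            table = sm.stats.anova_lm(fit, typ=2)
            others = [t for t in term.values() if t != term[effect]]
            rel = table.loc[others, "sum_sq"].max() / table["sum_sq"].sum()
            assert rel < 1e-8

    def test_incomplete_design_rejected(self):
        a = ["a1"] * 4 + ["a2"] * 2
        b = ["b1", "b1", "b2", "b2", "b1", "b1"]
        with pytest.raises(DesignError):
            rm.art_anova_2way(np.arange(6.0), a, b)


class TestIcc:
    def test_identical_raters(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = rm.icc_agreement(x, x)
        assert res.icc == pytest.approx(1.0)

    def test_agreement_penalizes_offset(self):
        rng = np.random.default_rng(10)
        x = rng.normal(10, 2, 50)
        agreement = rm.icc_agreement(x, x + 5.0)
        consistency = rm.icc_agreement(x, x + 5.0, form="consistency")
        assert agreement.icc < consistency.icc
        assert consistency.icc == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [11, 29, 47])
    def test_variance_ratio_recovery(self, seed):
        """ICC(A,1) recovers the analytic target s^2/(s^2+e^2) = 0.8."""
        table, manifest = rm.make_agreement_pairs(
            n=200, subject_sd=2.0, error_sd=1.0, seed=seed
        )
        res = rm.icc_agreement(table["rater1"], table["rater2"])
        assert res.icc == pytest.approx(manifest.values["icc_target"], abs=0.05)

    def test_matches_reference_implementation(self):
        """Cross-check the mean-squares formula against pingouin's ICC2."""
        pingouin = pytest.importorskip("pingouin")
        table, _ = rm.make_agreement_pairs(n=40, subject_sd=2.0, error_sd=1.0, seed=5)
        ours = rm.icc_agreement(table["rater1"], table["rater2"]).icc
        long = table.melt(
            id_vars="subject", value_vars=["rater1", "rater2"],
            var_name="rater", value_name="score",
        )
        ref = pingouin.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        )
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert ours == pytest.approx(icc2, abs=1e-6)

    def test_constant_data_flagged(self):
        res = rm.icc_agreement([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert not res.icc_defined
        assert np.isnan(res.icc)


class TestBlandAltman:
    def test_identical(self):
        a = np.array([1.0, 2.0, 3.0])
        res = rm.bland_altman(a, a)
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0
        assert res.slope == 0.0

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0])
        res = rm.bland_altman(a, a + 1.0)
        assert res.bias == pytest.approx(-1.0)
        assert res.sd_diff == pytest.approx(0.0)

    def test_proportional_bias_detected(self):
        a = np.linspace(1, 10, 30)
        res = rm.bland_altman(a, a * 1.1)
        # d = -0.1a on means of 1.05a: slope = -0.1/1.05
        assert res.slope == pytest.approx(-0.1 / 1.05, rel=1e-6)

    def test_loa_bracket_bias(self, rng):
        a = rng.normal(5, 1, 25)
        b = a + rng.normal(0.2, 0.3, 25)
        res = rm.bland_altman(a, b)
        assert res.loa_low <= res.bias <= res.loa_high


class TestNormalityVarianceGate:
    def test_normal_samples_pass(self):
        rng = np.random.default_rng(31)
        rejections = 0
        n_sim = 60
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, 30) for _ in range(3)]
            rep = rm.normality_variance_gate(groups)
            if rep["recommendation"] == "nonparametric":
                rejections += 1
        # under normality the gate should rarely push nonparametric
        # (4 tests at alpha 0.05 -> family rate well under half)
        assert rejections / n_sim < 0.5

    def test_exponential_rejected(self):
        rng = np.random.default_rng(17)
        hits = sum(
            rm.normality_variance_gate([rng.exponential(1, 50)] * 3)["shapiro_p"][0]
            < 0.05
            for _ in range(30)
        )
        assert hits / 30 > 0.9

    def test_equal_variance_accepted(self):
        rng = np.random.default_rng(23)
        ok = 0
        n_sim = 40
        for _ in range(n_sim):
            groups = [rng.normal(0, 1.0, 40) for _ in range(3)]
            if rm.normality_variance_gate(groups)["bartlett_p"] > 0.05:
                ok += 1
        assert ok / n_sim > 0.8

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            rm.normality_variance_gate([[1.0, 2.0]])
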