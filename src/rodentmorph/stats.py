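"""Nonparametric statistics and method-agreement analysis.

The cohort analyses are rank-based throughout: Kruskal-Wallis one-way
omnibus tests with post hoc comparisons (Tukey HSD on ranks, or pairwise
rank-sum tests) under Bonferroni correction, and aligned-rank-transform
(ART) two-way factorial tests for the meniscus design. Method agreement
uses the two-way absolute-agreement single-measurement intraclass
correlation ICC(A,1) and Bland-Altman bias with 95% limits of agreement.
Normality (Shapiro-Wilk) and homogeneity of variance (Bartlett) are
checked as a gate that is logged but never auto-switches the analysis.
"""

from __future__ import annotations

import itertools
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import AgreementResult, DesignError, StatResult

logger = logging.getLogger(__name__)

__all__ = [
    "kruskal_wallis",
    "posthoc_pairwise",
    "art_anova_2way",
    "rank_sum",
    "adjust_bonferroni",
    "icc_agreement",
    "bland_altman",
    "normality_variance_gate",
]

#: combined sample size at or below which rank-based tests use the exact
#: permutation/enumeration null instead of the large-sample approximation
EXACT_RANKSUM_N = 12
EXACT_KRUSKAL_N = 12


def _as_groups(groups: Sequence[Sequence[float]]) -> List[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(len(g) == 0 for g in out):
        raise ValueError("empty group")
    return out


def _kw_h(rank_sums: np.ndarray, sizes: np.ndarray, n: int, tie: float) -> float:
    h = 12.0 / (n * (n + 1)) * np.sum(rank_sums**2 / sizes) - 3 * (n + 1)
    return h / tie


def _kw_exact_p(gs: List[np.ndarray], h_obs: float) -> float:
    """Exact permutation p for the KW statistic by exhaustive enumeration
    of all distinct assignments of the pooled ranks to the groups."""
    pooled = np.concatenate(gs)
    ranks = sps.rankdata(pooled)
    sizes = np.array([len(g) for g in gs])
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / float(n**3 - n)

    extreme = total = 0

    def recurse(remaining: tuple, level: int, sums: list) -> None:
        nonlocal extreme, total
        if level == len(sizes) - 1:
            all_sums = np.array(sums + [sum(remaining)])
            h = _kw_h(all_sums, sizes, n, tie)
            total += 1
            if h >= h_obs - 1e-12:
                extreme += 1
            return
        for combo in itertools.combinations(range(len(remaining)), sizes[level]):
            picked = sum(remaining[i] for i in combo)
            rest = tuple(
                remaining[i] for i in range(len(remaining)) if i not in set(combo)
            )
            recurse(rest, level + 1, sums + [picked])

    recurse(tuple(ranks), 0, [])
    return extreme / total


def kruskal_wallis(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> StatResult:
    """Kruskal-Wallis H test on k independent samples.

    H is computed on midranks with tie correction. For combined n at or
    below 12 the p-value comes from the exact permutation distribution
    (exhaustive enumeration of rank assignments); beyond that, from the
    chi-square approximation with k-1 degrees of freedom. With no
    variation at all (every observation identical) the tie-corrected
    convention H = 0, p = 1 is returned.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    df = len(gs) - 1
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        return StatResult("kruskal_wallis", 0.0, df, 1.0, alpha=alpha)
    h, p = sps.kruskal(*gs)
    if len(pooled) <= EXACT_KRUSKAL_N:
        p = _kw_exact_p(gs, float(h))
    return StatResult("kruskal_wallis", float(h), df, float(p), alpha=alpha)


def rank_sum(
    x: Sequence[float], y: Sequence[float], paired: bool = False, alpha: float = 0.05
) -> StatResult:
    """Two-sided rank-sum test.

    Unpaired: Wilcoxon rank-sum (Mann-Whitney), exact null distribution
    for combined n <= 12 without ties, otherwise the normal approximation
    with continuity correction; ties use midranks. Paired: Wilcoxon
    signed-rank on the differences (identical pairs give p = 1).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            return StatResult("wilcoxon_signed_rank", 0.0, len(x), 1.0, alpha=alpha)
        stat, p = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
        return StatResult("wilcoxon_signed_rank", float(stat), len(x), float(p), alpha=alpha)
    n_comb = len(x) + len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n_comb
    method = "exact" if (n_comb <= EXACT_RANKSUM_N and not has_ties) else "asymptotic"
    stat, p = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return StatResult("rank_sum", float(stat), (len(x), len(y)), float(p), alpha=alpha)


def adjust_bonferroni(p_values: Sequence[float]) -> List[float]:
    """Bonferroni correction: multiply by the family size, cap at 1."""
    ps = [float(p) for p in p_values]
    if any(not (0.0 <= p <= 1.0) for p in ps):
        raise ValueError("p values must lie in [0, 1]")
    m = len(ps)
    return [min(1.0, p * m) for p in ps]


def posthoc_pairwise(
    groups: Sequence[Sequence[float]],
    method: str = "tukey_on_ranks",
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> List[StatResult]:
    """All k(k-1)/2 pairwise comparisons after a significant omnibus test.

    ``tukey_on_ranks`` applies Tukey's HSD (studentized-range p-values) to
    the pooled midranks of the data; ``rank_sum`` runs pairwise two-sided
    rank-sum tests. Either way the raw p-values are then Bonferroni
    adjusted over the family of comparisons.
    """
    gs = _as_groups(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match group count")
    pairs = list(itertools.combinations(range(k), 2))

    if method == "tukey_on_ranks":
        pooled = np.concatenate(gs)
        if np.ptp(pooled) == 0:
            results = [
                StatResult("tukey_on_ranks", 0.0, (k, len(pooled) - k), 1.0,
                           alpha=alpha, label=f"{labels[i]} vs {labels[j]}")
                for i, j in pairs
            ]
            return results
        ranks = sps.rankdata(pooled)
        codes = np.concatenate([[i] * len(g) for i, g in enumerate(gs)])
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        hsd = pairwise_tukeyhsd(ranks, codes, alpha=alpha)
        # statsmodels orders pairs exactly as itertools.combinations
        results = [
            StatResult(
                "tukey_on_ranks",
                float(hsd.meandiffs[m]),
                (k, len(pooled) - k),
                float(hsd.pvalues[m]),
                alpha=alpha,
                label=f"{labels[i]} vs {labels[j]}",
            )
            for m, (i, j) in enumerate(pairs)
        ]
    elif method == "rank_sum":
        results = []
        for i, j in pairs:
            r = rank_sum(gs[i], gs[j], alpha=alpha)
            r.label = f"{labels[i]} vs {labels[j]}"
            results.append(r)
    else:
        raise ValueError(f"unknown post hoc method {method!r}")

    adj = adjust_bonferroni([r.p_value for r in results])
    for r, pa in zip(results, adj):
        r.p_adjusted = pa
    return results


def _check_complete(df: pd.DataFrame) -> None:
    counts = df.groupby(["a", "b"], observed=True).size()
    n_a = df["a"].nunique()
    n_b = df["b"].nunique()
    if len(counts) != n_a * n_b:
        missing = set(itertools.product(df["a"].unique(), df["b"].unique())) - set(
            counts.index
        )
        raise DesignError(f"incomplete two-factor layout; missing cells {sorted(missing)}")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise DesignError(f"cells with fewer than 2 replicates: {bad}")


def align_for_effect(
    values: np.ndarray, factor_a: np.ndarray, factor_b: np.ndarray, effect: str
) -> np.ndarray:
    """Aligned responses for one effect of a two-factor layout.

    Alignment strips the estimated contributions of every other effect:
    for a main effect the cell mean is removed and that factor's marginal
    mean restored; for the interaction both marginal means are removed.
    After aligning for effect X, a factorial ANOVA on the aligned data
    shows (near-)zero sums of squares for every effect except X.
    """
    df = pd.DataFrame({"y": values, "a": factor_a, "b": factor_b})
    cell = df.groupby(["a", "b"], observed=True)["y"].transform("mean")
    mean_a = df.groupby("a", observed=True)["y"].transform("mean")
    mean_b = df.groupby("b", observed=True)["y"].transform("mean")
    grand = df["y"].mean()
    resid = df["y"] - cell
    if effect == "a":
        aligned = resid + mean_a
    elif effect == "b":
        aligned = resid + mean_b
    elif effect == "a:b":
        aligned = resid + (cell - mean_a - mean_b + grand)
    else:
        raise ValueError(f"unknown effect {effect!r}")
    return aligned.to_numpy()


def art_anova_2way(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
    alpha: float = 0.05,
    names: Tuple[str, str] = ("A", "B"),
) -> Dict[str, StatResult]:
    """Aligned rank transform (ART) two-way factorial test.

    For each effect (A, B, A x B) the response is aligned for that effect,
    the aligned values are midranked over all observations, a two-way
    factorial ANOVA is fitted to the ranks, and only that effect's F, df,
    and p are reported. With no variation at all, F = 0 and p = 1 for
    every effect.
    """
    y = np.asarray(values, dtype=float).ravel()
    a = np.asarray(factor_a).ravel()
    b = np.asarray(factor_b).ravel()
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factors must have equal length")
    df = pd.DataFrame({"y": y, "a": a.astype(str), "b": b.astype(str)})
    _check_complete(df)

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    effects = {"a": names[0], "b": names[1], "a:b": f"{names[0]}:{names[1]}"}
    anova_terms = {"a": "C(a)", "b": "C(b)", "a:b": "C(a):C(b)"}
    out: Dict[str, StatResult] = {}
    for effect, label in effects.items():
        if np.ptp(y) == 0:
            df_num = (df["a"].nunique() - 1) * (df["b"].nunique() - 1) if effect == "a:b" else (
                df["a" if effect == "a" else "b"].nunique() - 1
            )
            df_den = len(y) - df["a"].nunique() * df["b"].nunique()
            out[label] = StatResult(f"ART({label})", 0.0, (df_num, df_den), 1.0, alpha=alpha)
            continue
        aligned = align_for_effect(y, df["a"].to_numpy(), df["b"].to_numpy(), effect)
        ranked = sps.rankdata(aligned)
        fit = smf.ols("r ~ C(a) * C(b)", data=df.assign(r=ranked)).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        row = table.loc[anova_terms[effect]]
        df_num = float(row["df"])
        df_den = float(table.loc["Residual", "df"])
        fval = float(row["F"])
        pval = float(row["PR(>F)"])
        if not np.isfinite(fval):  # aligned ranks constant for this effect
            fval, pval = 0.0, 1.0
        out[label] = StatResult(
            f"ART({label})", fval, (df_num, df_den), pval, alpha=alpha, label=label
        )
    return out


def icc_agreement(
    rater1: Sequence[float],
    rater2: Sequence[float],
    form: str = "agreement",
    alpha: float = 0.05,
) -> AgreementResult:
    """Two-way single-measurement intraclass correlation between 2 raters.

    ``form='agreement'`` gives the absolute-agreement coefficient ICC(A,1)
    from the two-way (subjects x raters) mean squares::

        ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k/n (MS_C - MS_E))

    with k = 2 raters and n subjects; ``form='consistency'`` gives
    ICC(C,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E), which ignores a fixed
    rater offset. Constant data across both raters leaves the coefficient
    undefined: the result carries ``icc_defined=False`` and icc = nan.
    """
    x = np.asarray(rater1, dtype=float).ravel()
    y = np.asarray(rater2, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("raters must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if form not in ("agreement", "consistency"):
        raise ValueError("form must be 'agreement' or 'consistency'")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    ba = bland_altman(x, y)
    if ss_total == 0:
        logger.warning("constant data across both raters; ICC undefined")
        ba.icc = float("nan")
        ba.icc_defined = False
        return ba
    if form == "agreement":
        denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    else:
        denom = ms_r + (k - 1) * ms_e
    ba.icc = float((ms_r - ms_e) / denom)
    ba.icc_defined = True
    return ba


def bland_altman(a: Sequence[float], b: Sequence[float]) -> AgreementResult:
    """Bland-Altman agreement: bias, 95% limits, proportional-bias slope.

    Differences are ``d = a - b``; bias = mean(d); the limits of agreement
    are bias +/- 1.96 x SD(d) (sample SD); the proportional-bias slope is
    the least-squares slope of d on the pairwise means (0 when the SD of
    d is 0 or n < 3).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    means = 0.5 * (a + b)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if n >= 3 and np.ptp(means) > 0 and sd > 0:
        slope = float(np.polyfit(means, d, 1)[0])
    else:
        slope = 0.0
    return AgreementResult(
        n_pairs=n,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        slope=slope,
        means=means,
        diffs=d,
    )


def normality_variance_gate(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> dict:
    """Shapiro-Wilk normality per group and Bartlett homogeneity pooled.

    Returns per-group Shapiro p-values, the Bartlett p-value, and a
    recommendation flag ('parametric' only when no test rejects at
    ``alpha``). The pipeline logs the recommendation but never switches
    tests automatically.
    """
    gs = _as_groups(groups)
    if any(len(g) < 3 for g in gs):
        raise ValueError("each group needs n >= 3 for the gate")
    shapiro_ps = []
    for g in gs:
        if np.ptp(g) == 0:
            shapiro_ps.append(0.0)  # degenerate: certainly non-normal
        else:
            shapiro_ps.append(float(sps.shapiro(g).pvalue))
    if all(np.ptp(g) > 0 for g in gs):
        stat, bartlett_p = sps.bartlett(*gs)
        # exactly equal variances give a 0/0 inside scipy; the evidence
        # against homogeneity is then nil
        bartlett_p = 1.0 if np.isnan(bartlett_p) and stat == 0 else float(bartlett_p)
    else:
        bartlett_p = float("nan")
    ok = all(p >= alpha for p in shapiro_ps) and (
        np.isnan(bartlett_p) or bartlett_p >= alpha
    )
    rec = "parametric" if ok else "nonparametric"
    logger.info("normality/variance gate recommends %s analysis", rec)
    return {
        "shapiro_p": shapiro_ps,
        "bartlett_p": bartlett_p,
        "recommendation": rec,
        "alpha": alpha,
    }
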