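"""Cross-species expression divergence statistics.

Per-metagene differential expression uses a Welch two-sample t-test on
normalized log expression with Benjamini–Hochberg FDR control (q = 0.001 in
the main analysis).  Divergence of the highly expressed gene repertoire is
measured as the overlap in identity of each species' top 5% genes (by median
rank across replicates), summarized either per tissue pair (overlap matrix)
or as a rank concordance curve: for each rank k, the fraction of species-A
genes at rank <= k whose species-B ortholog is also at rank <= k, with exact
binomial (Clopper–Pearson) confidence bands Bonferroni-adjusted over the 500
ranks examined.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "welch_ttest_table",
    "bh_fdr",
    "median_ranks",
    "median_rank_top_set",
    "overlap_fraction",
    "overlap_matrix",
    "arcsine_one_sample_test",
    "rank_concordance_curve",
    "binomial_ci_bonferroni",
    "two_proportion_test",
    "ConcordanceCurve",
]


def bh_fdr(p_values: Sequence[float], q: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values outside [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def welch_ttest_table(
    expr_a: pd.DataFrame, expr_b: pd.DataFrame, q: float = 0.001
) -> pd.DataFrame:
    """Row-wise Welch t-test between two species' replicate matrices.

    Both matrices must share the same metagene index and have >= 2 replicate
    columns. Rows with zero variance in both groups and equal means get
    t = 0, p = 1. Returns a table with group means, t, p, BH-adjusted p, the
    FDR flag at ``q``, and each species' median expression rank (1 = highest).
    """
    if not expr_a.index.equals(expr_b.index):
        raise ValueError("expression matrices must share the same row index")
    if expr_a.shape[1] < 2 or expr_b.shape[1] < 2:
        raise ValueError("each species needs >= 2 replicate arrays")
    a = expr_a.to_numpy(dtype=float)
    b = expr_b.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # both groups constant: equal means -> no evidence (t=0, p=1);
    # unequal means -> perfect separation (p=0)
    flat = np.isnan(t)
    if flat.any():
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        t[flat & same] = 0.0
        p[flat & same] = 1.0
        t[flat & ~same] = np.inf
        p[flat & ~same] = 0.0
    reject, p_adj = bh_fdr(p, q)
    return pd.DataFrame(
        {
            "mean_A": a.mean(axis=1),
            "mean_B": b.mean(axis=1),
            "t_stat": t,
            "p_value": p,
            "p_adjusted": p_adj,
            "q_flag": reject,
            "median_rank_A": median_ranks(expr_a),
            "median_rank_B": median_ranks(expr_b),
        },
        index=expr_a.index,
    )


def median_ranks(expr: pd.DataFrame) -> pd.Series:
    """Median across replicates of the within-array expression rank (1 = highest).

    Ties receive average (fractional) ranks.
    """
    ranks = np.apply_along_axis(
        lambda col: stats.rankdata(-col, method="average"), 0, expr.to_numpy(float)
    )
    return pd.Series(np.median(ranks, axis=1), index=expr.index, name="median_rank")


def median_rank_top_set(expr: pd.DataFrame, fraction: float = 0.05) -> set:
    """The top ``fraction`` of rows by median expression rank.

    Takes the floor(fraction*N) rows with smallest median rank, expanded to
    include every row tied at the boundary (deterministic, order-independent).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if expr.shape[0] == 0:
        raise ValueError("empty expression matrix")
    mr = median_ranks(expr)
    n_top = int(np.floor(fraction * len(mr)))
    if n_top == 0:
        return set()
    threshold = np.sort(mr.to_numpy())[n_top - 1]
    return set(mr.index[mr.to_numpy() <= threshold])


def overlap_fraction(set_a: set, set_b: set, denominator: str = "A") -> float:
    """|A ∩ B| divided by the size of the chosen species' own top set."""
    denom = set_a if denominator == "A" else set_b
    if not denom:
        raise ValueError("empty denominator set")
    return len(set_a & set_b) / len(denom)


def overlap_matrix(
    expr_by_tissue: Mapping[str, pd.DataFrame], fraction: float = 0.05
) -> pd.DataFrame:
    """Pairwise top-fraction overlap between tissues/transcriptomes.

    Entry (i, j) is |top_i ∩ top_j| / |top_i|; the diagonal is 1. All
    matrices must be restricted to the same ortholog universe.
    """
    names = list(expr_by_tissue)
    universe = None
    tops = {}
    for name, expr in expr_by_tissue.items():
        idx = frozenset(expr.index)
        if universe is None:
            universe = idx
        elif idx != universe:
            raise ValueError(f"tissue {name!r} has a mismatched gene universe")
        tops[name] = median_rank_top_set(expr, fraction)
    out = pd.DataFrame(index=names, columns=names, dtype=float)
    for i in names:
        for j in names:
            out.loc[i, j] = (
                1.0 if i == j else overlap_fraction(tops[i], tops[j], "A")
            )
    return out


def arcsine_one_sample_test(
    reference_overlap: float, tissue_overlaps: Sequence[float]
) -> tuple[float, float]:
    """One-sample t-test of arcsin(sqrt(p))-transformed overlap fractions.

    Tests whether the tissue overlap fractions differ from a reference
    overlap (e.g. the dendrite overlap) after the variance-stabilizing
    arcsine-square-root transform.
    """
    vals = np.asarray(tissue_overlaps, dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 tissue overlaps")
    all_vals = np.append(vals, reference_overlap)
    if ((all_vals < 0) | (all_vals > 1)).any():
        raise ValueError("overlap fractions must be in [0, 1]")
    transformed = np.arcsin(np.sqrt(vals))
    ref = np.arcsin(np.sqrt(reference_overlap))
    if np.allclose(transformed, ref):
        return 0.0, 1.0
    res = stats.ttest_1samp(transformed, popmean=ref)
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass
class ConcordanceCurve:
    """Rank concordance curve with Bonferroni-adjusted exact binomial bands."""

    k: np.ndarray
    concordance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_k: np.ndarray
    bonferroni_factor: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "concordance": self.concordance,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_at_k": self.n_at_k,
            }
        )


def binomial_ci_bonferroni(
    successes: int, n: int, level: float = 0.95, factor: int = 500
) -> tuple[float, float]:
    """Clopper–Pearson binomial CI at Bonferroni-adjusted level 1-(1-level)/factor.

    The exact interval is used because the number of trials can be as small
    as the lowest rank examined (31), where the normal approximation fails.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    alpha = (1.0 - level) / factor
    low = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return low, high


def rank_concordance_curve(
    score_a: pd.Series,
    score_b: pd.Series,
    k_min: int = 31,
    k_max: int = 500,
    level: float = 0.95,
    bonferroni_factor: int = 500,
) -> ConcordanceCurve:
    """Fraction of species-A top-k genes whose B ortholog is also at rank <= k.

    ``score_a`` and ``score_b`` hold one expression score per ortholog
    (indexes must match pair for pair, e.g. via metagene ids). Ranks use
    average ranks for ties, rank 1 = highest expression. For each k in
    [k_min, k_max] the concordance is the fraction, among A genes with rank
    <= k, whose ortholog's B rank is <= k; its CI is exact binomial at the
    Bonferroni-adjusted level.
    """
    if not score_a.index.equals(score_b.index):
        raise ValueError("ortholog score series must share the same index")
    n_genes = len(score_a)
    if k_max >= n_genes:
        raise ValueError(f"k_max ({k_max}) must be < number of orthologs ({n_genes})")
    rank_a = stats.rankdata(-score_a.to_numpy(float), method="average")
    rank_b = stats.rankdata(-score_b.to_numpy(float), method="average")
    ks = np.arange(k_min, k_max + 1)
    conc = np.empty(ks.size)
    lo = np.empty(ks.size)
    hi = np.empty(ks.size)
    n_at_k = np.empty(ks.size, dtype=int)
    order = np.argsort(rank_a, kind="stable")
    ra_sorted = rank_a[order]
    rb_sorted = rank_b[order]
    for i, k in enumerate(ks):
        m = int(np.searchsorted(ra_sorted, k, side="right"))
        if m == 0:
            conc[i], lo[i], hi[i], n_at_k[i] = np.nan, np.nan, np.nan, 0
            continue
        x = int(np.count_nonzero(rb_sorted[:m] <= k))
        conc[i] = x / m
        lo[i], hi[i] = binomial_ci_bonferroni(x, m, level, bonferroni_factor)
        n_at_k[i] = m
    return ConcordanceCurve(ks, conc, lo, hi, n_at_k, bonferroni_factor)


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, method: str = "z-pooled"
) -> float:
    """Two-sided test of equal proportions x1/n1 vs x2/n2.

    ``method`` is one of ``z-pooled`` (score test without continuity
    correction; equal observed proportions give p = 1), ``chisq``
    (equivalent Pearson chi-square) or ``exact`` (Fisher). The variants can
    disagree noticeably at small counts, which is why all three are exposed.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError("counts must be in [0, n]")
    if method == "z-pooled":
        p1, p2 = x1 / n1, x2 / n2
        pooled = (x1 + x2) / (n1 + n2)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        if se == 0:
            return 1.0
        z = (p1 - p2) / se
        return float(2 * stats.norm.sf(abs(z)))
    if method == "chisq":
        table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
        if table.sum(axis=0).min() == 0:
            return 1.0
        return float(stats.chi2_contingency(table, correction=False).pvalue)
    if method == "exact":
        table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
        return float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    raise ValueError(f"unknown method {method!r}")
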