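"""Differential expression stand-in, promoter-occupancy summaries, Z-scores,
and the one-sided rank-sum test used for loop-expression comparisons.

The DE stage mirrors the common count-based workflow: library-size
normalization, per-gene negative-binomial Wald test with moment-based
dispersion, and the standard thresholds (FDR < 0.01 and linear fold
change > 1.5 in either direction) for calling a gene up / down /
unchanged.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dynamics import _nb_wald, pooled_dispersion

__all__ = [
    "simple_de",
    "promoter_peak_expression_summary",
    "lineage_zscore",
    "rank_test_one_sided",
]


def _median_of_ratios(mat: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (robust to asymmetric DE).

    Ratios are taken to the per-gene geometric mean over samples, using
    genes expressed in every sample; falls back to total-count scaling
    when no such gene exists.
    """
    pos = (mat > 0).all(axis=1)
    if not pos.any():
        totals = mat.sum(axis=0)
        return totals / totals.mean()
    log_ref = np.log(mat[pos]).mean(axis=1, keepdims=True)
    size = np.exp(np.median(np.log(mat[pos]) - log_ref, axis=0))
    return size / size.mean()


def simple_de(
    counts: pd.DataFrame,
    cond_a_cols: list[str],
    cond_b_cols: list[str],
    fdr: float = 0.01,
    min_fold: float = 1.5,
) -> pd.DataFrame:
    """NB Wald differential expression between two conditions.

    ``counts`` is genes x samples (raw counts).  The library-size factor
    enters the NB regression as an offset; the fold change is on
    normalized means (condition B over A).  Genes pass only with
    BH FDR < ``fdr`` AND linear fold > ``min_fold``; all-zero genes stay
    unchanged and are flagged.
    """
    if len(cond_a_cols) < 2 or len(cond_b_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    cols = list(cond_a_cols) + list(cond_b_cols)
    mat = counts[cols].to_numpy(dtype=float)
    totals = mat.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a sample has zero total counts")
    size = _median_of_ratios(mat)
    cond = np.array([0] * len(cond_a_cols) + [1] * len(cond_b_cols))
    offset = np.log(size)

    n_genes = mat.shape[0]
    pvals = np.ones(n_genes)
    coefs = np.zeros(n_genes)
    all_zero = mat.sum(axis=1) == 0
    # dispersion is shared across genes (median of gene-wise moment
    # estimates): row-wise estimates at 2-3 replicates are too noisy to
    # support the Wald reference
    alpha = pooled_dispersion([(mat[g], cond, offset)
                               for g in range(n_genes) if not all_zero[g]])
    for g in range(n_genes):
        if all_zero[g]:
            continue
        coefs[g], pvals[g] = _nb_wald(mat[g], cond, offset, alpha=alpha)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    norm = mat / size
    mean_a = norm[:, : len(cond_a_cols)].mean(axis=1)
    mean_b = norm[:, len(cond_a_cols):].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = (mean_b + 0.5) / (mean_a + 0.5)
    big = np.maximum(fold, 1 / fold) > min_fold
    sig = (qvals < fdr) & big & ~all_zero
    label = np.where(sig & (fold > 1), "up", np.where(sig & (fold < 1), "down", "unchanged"))
    out = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b,
        "log2_fold": np.log2(fold), "coef": coefs,
        "pvalue": pvals, "qvalue": qvals, "label": label, "all_zero": all_zero,
    }, index=counts.index)
    return out


def promoter_peak_expression_summary(
    peaks: pd.DataFrame,
    gene_models: pd.DataFrame,
    expression: pd.DataFrame,
    promoter_halfwidth: int = 3_000,
) -> dict:
    """Fraction of promoter-bound genes whose expression is unchanged.

    Cognate genes are those whose +/- ``promoter_halfwidth`` promoter
    window overlaps any peak; the summary reports how many of them carry
    the DE label ``unchanged``.
    """
    if "label" not in expression.columns:
        raise ValueError("expression table must carry DE labels")
    cognate = []
    for gid, g in gene_models.iterrows():
        p_start = int(g["tss"]) - promoter_halfwidth
        p_end = int(g["tss"]) + promoter_halfwidth
        sub = peaks[peaks["chrom"] == g["chrom"]] if "chrom" in peaks.columns else peaks
        if len(sub) == 0:
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if ((s < p_end) & (e > p_start)).any():
            cognate.append(gid)
    cognate = [g for g in cognate if g in expression.index]
    if not cognate:
        raise ValueError("no cognate genes found at promoter peaks")
    labels = expression.loc[cognate, "label"]
    n_unchanged = int((labels == "unchanged").sum())
    n_total = len(cognate)
    return {
        "n_unchanged": n_unchanged,
        "n_total": n_total,
        "percent_unchanged": 100.0 * n_unchanged / n_total,
    }


def lineage_zscore(target_value: float, panel_values: np.ndarray, log_transform: bool = False) -> float:
    """Z of a target expression value against a multi-celltype panel.

    With ``log_transform`` the inputs are taken as FPKM and moved to
    log2(FPKM + 1) first.  A zero-spread panel yields signed infinity.
    """
    panel = np.asarray(panel_values, dtype=float)
    if panel.size < 2:
        raise ValueError("panel must contain >= 2 values")
    t = float(target_value)
    if log_transform:
        panel = np.log2(panel + 1)
        t = float(np.log2(t + 1))
    sd = panel.std(ddof=1)
    if sd == 0:
        return float(np.sign(t - panel.mean()) * np.inf) if t != panel.mean() else 0.0
    return float((t - panel.mean()) / sd)


def rank_test_one_sided(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alternative: str = "less",
    exact_max_n: int = 12,
) -> float:
    """One-sided Wilcoxon rank-sum p-value.

    ``alternative="less"`` tests whether ``group_a`` is stochastically
    smaller than ``group_b``.  For pooled sizes up to ``exact_max_n``
    the p-value is exact, by enumerating all C(n+m, n) assignments of
    the pooled values to group A (tie-safe); larger samples use the
    tie-corrected normal approximation.  When every value in both
    groups is identical the test is uninformative and 0.5 is returned
    by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.5
    n, m = a.size, b.size
    if n + m <= exact_max_n:
        ranks = stats.rankdata(pooled)
        obs = ranks[:n].sum()
        total = comb(n + m, n)
        count = 0
        idx = range(n + m)
        for combo in combinations(idx, n):
            s = ranks[list(combo)].sum()
            if alternative == "less":
                if s <= obs + 1e-9:
                    count += 1
            else:
                if s >= obs - 1e-9:
                    count += 1
        return count / total
    return float(stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic").pvalue)
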