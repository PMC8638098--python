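"""Simplified negative-binomial differential expression.

A deliberately small stand-in for a full NB GLM framework: counts
``K_ij ~ NB(mu_ij, alpha_i)`` with variance ``mu + alpha * mu**2``,
median-of-ratios size factors, per-gene method-of-moments dispersion,
a Wald test on the log fold change via the delta method, and
Benjamini-Hochberg adjustment.  There is no dispersion shrinkage,
outlier handling or independent filtering, so results on real data
will differ from a full DESeq2-style analysis; the simulation-based
calibration and power checks in the test suite quantify what this
stage does deliver.

The result table (``DEResult``) is a pandas DataFrame indexed by gene
id with columns ``base_mean``, ``log2_fold_change``, ``p_value`` and
``p_adjust``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import CountScenario

__all__ = [
    "filter_low_expressed",
    "size_factors",
    "nb_wald_test",
    "select_de_genes",
    "top_k_genes",
    "bh_adjust",
]

logger = logging.getLogger(__name__)

# Pseudocount added to group means before the fold change so sparse
# genes get a bounded log ratio.
PSEUDOCOUNT = 0.5
# Poisson-limit floor for the moment dispersion estimate.
DISPERSION_FLOOR = 1e-8

DEResult = pd.DataFrame  # columns: base_mean, log2_fold_change, p_value, p_adjust


def filter_low_expressed(counts: CountScenario, min_total: int) -> CountScenario:
    """Keep genes whose total count across samples is >= ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be nonnegative")
    keep = counts.counts.sum(axis=1) >= min_total
    if not keep.any():
        raise ValueError(
            f"min_total={min_total} removes every gene; lower the threshold"
        )
    old_to_new = {}
    new = 0
    for old, k in enumerate(keep):
        if k:
            old_to_new[old] = new
            new += 1
    return CountScenario(
        counts=counts.counts[keep],
        group_labels=list(counts.group_labels),
        de_genes={old_to_new[g] for g in counts.de_genes if keep[g]},
        true_lfc=counts.true_lfc[keep],
        dispersion=counts.dispersion[keep],
        seed=counts.seed,
        gene_ids=[g for g, k in zip(counts.gene_ids, keep) if k],
        sample_ids=list(counts.sample_ids),
    )


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalisation factors, one per sample.

    Per sample: the median over all-positive genes of the ratio of the
    gene's count to its across-sample geometric mean; the factors are
    then rescaled to geometric mean 1.  If no gene is positive in every
    sample the method degenerates and total-count (library-size)
    factors are used instead, with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.any():
        sub = counts[positive]
        geomean = np.exp(np.log(sub).mean(axis=1, keepdims=True))
        factors = np.median(sub / geomean, axis=0)
    else:
        logger.warning(
            "no gene has positive counts in every sample; "
            "falling back to total-count size factors"
        )
        totals = counts.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("a sample has zero total counts; cannot normalise")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def _two_group_masks(group_labels) -> tuple[np.ndarray, np.ndarray, str, str]:
    labels = list(group_labels)
    levels = sorted(set(labels))  # deterministic reference: alphabetical
    if len(levels) != 2:
        raise ValueError(f"exactly two groups are required, got {levels}")
    g1, g2 = levels
    m1 = np.array([lab == g1 for lab in labels])
    m2 = ~m1
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    return m1, m2, g1, g2


def nb_wald_test(
    counts: np.ndarray,
    group_labels,
    gene_ids: list[str] | None = None,
) -> DEResult:
    """Per-gene NB Wald test of the log fold change between two groups.

    Counts are normalised by median-of-ratios size factors; the log2
    fold change is ``log2((mean2 + pc) / (mean1 + pc))`` with
    pseudocount 0.5.  Per-gene dispersion is estimated by pooled
    within-group moments, ``alpha = (SS_resid - SS_mean) / SS_mu2``
    floored at the Poisson limit, the standard error of the natural-log
    fold change follows from ``var = mu + alpha mu**2`` through the
    log link, and the two-sided p-value is normal.  Genes with zero
    counts in both groups get p = 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a genes x samples matrix")
    m1, m2, _, _ = _two_group_masks(group_labels)
    if counts.shape[1] != len(list(group_labels)):
        raise ValueError("one group label per sample is required")
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(counts.shape[0])]

    sf = size_factors(counts)
    norm = counts / sf
    n1, n2 = int(m1.sum()), int(m2.sum())
    mu1 = norm[:, m1].mean(axis=1)
    mu2 = norm[:, m2].mean(axis=1)
    s1 = norm[:, m1].var(axis=1, ddof=1)
    s2 = norm[:, m2].var(axis=1, ddof=1)

    # Pooled method-of-moments dispersion: excess variance over the mean,
    # relative to mu^2, pooled across the two groups.
    num = (n1 - 1) * (s1 - mu1) + (n2 - 1) * (s2 - mu2)
    den = (n1 - 1) * mu1**2 + (n2 - 1) * mu2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    pc = PSEUDOCOUNT
    lfc = np.log2((mu2 + pc) / (mu1 + pc))
    lfc_nat = np.log((mu2 + pc) / (mu1 + pc))
    v1 = (mu1 + pc) + alpha * (mu1 + pc) ** 2
    v2 = (mu2 + pc) + alpha * (mu2 + pc) ** 2
    se = np.sqrt(v1 / (n1 * (mu1 + pc) ** 2) + v2 / (n2 * (mu2 + pc) ** 2))
    z = lfc_nat / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    # All-zero genes carry no evidence either way.
    degenerate = (mu1 == 0) & (mu2 == 0)
    p[degenerate] = 1.0
    res = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2_fold_change": lfc,
            "p_value": p,
            "p_adjust": bh_adjust(p),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return res


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de_genes(
    res: DEResult, p_adjust_max: float = 0.01, lfc_min: float = 2.0
) -> list[str]:
    """Genes with ``p_adjust < p_adjust_max`` and ``|lfc| > lfc_min``
    (strict inequalities on both thresholds)."""
    mask = (res["p_adjust"] < p_adjust_max) & (res["log2_fold_change"].abs() > lfc_min)
    return res.index[mask].tolist()


def top_k_genes(res: DEResult, k: int = 100) -> list[str]:
    """The k most significant genes: smallest p_adjust, ties broken by
    larger |log2 fold change|, then lexicographic gene id."""
    if k < 1:
        raise ValueError("k must be at least 1")
    order = res.assign(_abs_lfc=res["log2_fold_change"].abs()).sort_values(
        by=["p_adjust", "_abs_lfc", "gene_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return order.index[:k].tolist()
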