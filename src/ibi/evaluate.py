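"""Downstream comparison machinery: min-max normalization, genetic risk
scores, AUROC, ROC-curve comparison, rank correlation and top-set summaries.

A subject's genetic risk score (GRS) is the weighted sum of the top-k ranked
SNPs the subject actually carries — weights are the odds ratio for the GWAS
ranking and M_s,r for the individualized ranking — and GRS vectors are
min-max normalized across the evaluated cohort before AUROC computation.
ROC curves are compared with a paired, stratified bootstrap of the AUC
difference by default; the DeLong variance method is available as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from ibi.types import GenotypeMatrix

__all__ = [
    "minmax_normalize",
    "grs",
    "random_ranking",
    "auroc",
    "RocComparison",
    "compare_roc",
    "rank_correlation",
    "top_set_summary",
]


def minmax_normalize(
    values: np.ndarray, lo: float, hi: float, clip: bool = False
) -> np.ndarray:
    """Affine map sending ``lo`` to 0 and ``hi`` to 1: ``(lo - x)/(lo - hi)``.

    The orientation is set purely by the roles of ``lo`` and ``hi`` (swap
    them to flip it); with ``lo > hi`` the map is order-reversing, as used
    when normalizing log marginals whose maximum should map to 0.
    """
    if hi == lo:
        raise ValueError("degenerate normalization bounds (hi == lo)")
    x = np.asarray(values, dtype=np.float64)
    out = (lo - x) / (lo - hi)
    return np.clip(out, 0.0, 1.0) if clip else out


def grs(
    genotypes: GenotypeMatrix,
    snp_order: np.ndarray,
    weights: np.ndarray,
    k: int = 1,
    normalize: bool = True,
) -> np.ndarray:
    """Per-subject genetic risk score from the top-k carried SNPs.

    ``snp_order`` lists SNP indices best-first under the chosen ranking;
    ``weights`` aligns with the genotype columns (not with ``snp_order``).
    Each subject sums the weights of the first ``k`` SNPs of ``snp_order``
    that they carry; subjects carrying fewer than ``k`` panel SNPs sum what
    exists (a subject carrying none scores 0).  With ``normalize`` the
    scores are min-max normalized across the cohort (min -> 0, max -> 1).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    order = np.asarray(snp_order, dtype=np.int64)
    w = np.asarray(weights, dtype=np.float64)
    g_ord = genotypes.values[:, order] == 1
    w_ord = w[order]
    scores = np.zeros(genotypes.n_subjects)
    for i in range(genotypes.n_subjects):
        carried = np.flatnonzero(g_ord[i])[:k]
        scores[i] = w_ord[carried].sum()
    if normalize:
        lo, hi = scores.min(), scores.max()
        if hi == lo:
            return np.zeros_like(scores)
        scores = minmax_normalize(scores, lo, hi)
    return scores


def random_ranking(n_snps: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """A random SNP ordering with unit weights — the null GRS baseline."""
    rng = np.random.default_rng(seed)
    return rng.permutation(n_snps), np.ones(n_snps)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney, ties count 1/2)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


@dataclass
class RocComparison:
    auc_a: float
    auc_b: float
    delta: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must lie in (0, 1]")


def compare_roc(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocComparison:
    """Two-sided test of AUC_a == AUC_b for two scores of the same subjects.

    ``bootstrap`` resamples cases and controls separately (paired across the
    two score vectors) and reports a two-sided bootstrap p-value for the AUC
    difference, with add-one smoothing so p stays in (0, 1].  ``delong``
    uses the DeLong covariance of the paired AUCs and a normal reference;
    when the DeLong variance of the difference is 0 (e.g. identical scores)
    the p-value is 1.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    y = np.asarray(labels)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("score vectors and labels must have equal length")
    auc_a, auc_b = auroc(a, y), auroc(b, y)
    delta = auc_a - auc_b
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        cases = np.flatnonzero(y == 1)
        controls = np.flatnonzero(y == 0)
        le = ge = 0
        for _ in range(n_boot):
            idx = np.concatenate(
                [
                    rng.choice(cases, size=len(cases), replace=True),
                    rng.choice(controls, size=len(controls), replace=True),
                ]
            )
            d = auroc(a[idx], y[idx]) - auroc(b[idx], y[idx])
            le += d <= 0
            ge += d >= 0
        p = 2.0 * min(le + 1, ge + 1) / (n_boot + 1)
        p = min(p, 1.0)
    elif method == "delong":
        var = _delong_var_diff(a, b, y)
        if var <= 0:
            p = 1.0
        else:
            z = delta / np.sqrt(var)
            p = max(float(2 * stats.norm.sf(abs(z))), np.finfo(float).tiny)
    else:
        raise ValueError(f"unknown method {method!r}")
    return RocComparison(auc_a=auc_a, auc_b=auc_b, delta=delta, p_value=p, method=method)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_var_diff(a: np.ndarray, b: np.ndarray, y: np.ndarray) -> float:
    """DeLong variance of AUC_a - AUC_b for paired scores."""
    pos = y == 1
    m, n = int(pos.sum()), int((~pos).sum())
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for i, s in enumerate((a, b)):
        r_all = _midrank(s)
        r_pos = _midrank(s[pos])
        r_neg = _midrank(s[~pos])
        v10[i] = (r_all[pos] - r_pos) / n
        v01[i] = 1.0 - (r_all[~pos] - r_neg) / m
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    cov = s10 / m + s01 / n
    return float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])


def rank_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks on ties."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation is undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def top_set_summary(
    scores: pd.DataFrame, gwas: pd.DataFrame, n_top: int
) -> dict:
    """Overlap and MAF profile of the top-n sets by M_s,r vs by p-value.

    Returns the intersection size and the MAF vectors of the
    individualized-only, GWAS-only and shared top SNPs.
    """
    if n_top > len(scores) or n_top > len(gwas):
        raise ValueError("n_top exceeds the panel size")
    top_ibi = set(scores.index[scores["rank_msr"] <= n_top])
    top_gwas = set(gwas.index[gwas["rank_p"] <= n_top])
    shared = top_ibi & top_gwas
    maf = scores["maf"]
    return {
        "n_top": n_top,
        "intersection": len(shared),
        "ibi_only_maf": maf.loc[sorted(top_ibi - top_gwas)].to_numpy(),
        "gwas_only_maf": maf.loc[sorted(top_gwas - top_ibi)].to_numpy(),
        "shared_maf": maf.loc[sorted(shared)].to_numpy(),
    }
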