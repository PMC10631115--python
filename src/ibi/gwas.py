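"""Population-level baseline: per-SNP Fisher's exact test and patient coverage.

Each SNP's 2x2 carrier-by-case table is tested with the two-sided Fisher's
exact test (point-probability convention: the p-value sums the probabilities
of all tables at least as extreme as the observed one under the
hypergeometric null).  The odds ratio reported is the sample (unconditional)
OR ``n11*n00 / (n10*n01)``, which later weights the GWAS genetic risk score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ibi.types import GenotypeMatrix, TraitVector

__all__ = [
    "fisher_test",
    "gwas_scan",
    "bonferroni_threshold",
    "assign_top1_gwas",
    "significant_patient_coverage",
]


def fisher_test(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher's exact p-value and sample odds ratio of a 2x2 table.

    Table layout: rows = carrier/non-carrier, columns = case/control, i.e.
    ``[[n11, n10], [n01, n00]]``.  The odds ratio is
    ``n11*n00 / (n10*n01)``, +inf when the denominator is 0.  A zero row or
    column margin makes the test undefined and raises.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("a zero margin makes Fisher's exact test undefined")
    p = float(stats.fisher_exact(t, alternative="two-sided").pvalue)
    n11, n10 = t[0]
    n01, n00 = t[1]
    denom = n10 * n01
    odds = float(n11 * n00) / denom if denom else np.inf
    return p, odds


def gwas_scan(genotypes: GenotypeMatrix, trait: TraitVector) -> pd.DataFrame:
    """Fisher's exact test for every SNP against the binary trait.

    Returns the SNP metadata plus the contingency counts (n11 = carrier
    cases, n10 = carrier controls, n01 = non-carrier cases, n00 = non-carrier
    controls), ``p``, ``odds_ratio`` and ``rank_p`` (rank 1 = smallest
    p-value, ties to the smaller SNP index).
    """
    g = genotypes.values
    t = np.asarray(trait.htn)
    if g.shape[0] != len(t):
        raise ValueError("genotypes and trait cover different numbers of subjects")
    n11 = ((g == 1) & (t[:, None] == 1)).sum(axis=0)
    n10 = ((g == 1) & (t[:, None] == 0)).sum(axis=0)
    n01 = ((g == 0) & (t[:, None] == 1)).sum(axis=0)
    n00 = ((g == 0) & (t[:, None] == 0)).sum(axis=0)
    p = np.empty(genotypes.n_snps)
    odds = np.empty(genotypes.n_snps)
    for s in range(genotypes.n_snps):
        p[s], odds[s] = fisher_test([[n11[s], n10[s]], [n01[s], n00[s]]])
    out = genotypes.snps.copy()
    out["n11"], out["n10"], out["n01"], out["n00"] = n11, n10, n01, n00
    out["p"] = p
    out["odds_ratio"] = odds
    order = np.lexsort((np.arange(len(p)), p))
    ranks = np.empty(len(p), dtype=np.int64)
    ranks[order] = np.arange(1, len(p) + 1)
    out["rank_p"] = ranks
    return out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance level ``alpha / n_tests``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def assign_top1_gwas(gwas: pd.DataFrame, patient_genotype: np.ndarray) -> int:
    """The carried SNP with the smallest p-value (ties -> smaller SNP index)."""
    geno = np.asarray(patient_genotype)
    if len(geno) != len(gwas):
        raise ValueError("patient genotype does not match the GWAS table")
    carried = np.flatnonzero(geno == 1)
    if len(carried) == 0:
        raise ValueError("patient carries no minor alleles to explain the trait")
    p = gwas["p"].to_numpy()[carried]
    return int(carried[np.argmin(p)])  # argmin keeps the first (smallest index)


def significant_patient_coverage(
    gwas: pd.DataFrame,
    case_genotypes: GenotypeMatrix,
    threshold: float,
) -> float:
    """Fraction of case subjects carrying at least one SNP with p < threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    sig = gwas["p"].to_numpy() < threshold
    covered = (case_genotypes.values[:, sig] == 1).any(axis=1)
    return float(covered.mean()) if len(covered) else 0.0
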