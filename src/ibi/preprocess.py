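"""Cohort preparation: mode imputation, dominant coding, the risk-allele
filter, D'-based LD pruning, hypertension derivation and the stratified split.

The pipeline mirrors standard case-control practice for dominant-coded data:
missing genotypes are filled with the SNP's modal value, diploid minor-allele
counts are collapsed to carrier status, "protective" SNPs (minor-allele risk
ratio < 1) are removed, and one SNP of every high-LD pair within a genomic
window is pruned.  Hypertension is defined as SBP >= 140 mmHg or DBP >= 90
mmHg or use of antihypertensive medication, after adding 10/5 mmHg to the
SBP/DBP of medicated subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ibi.types import MISSING, GenotypeMatrix, TraitVector

__all__ = [
    "impute_mode",
    "dominant_code",
    "risk_ratio_filter",
    "dprime",
    "ld_prune",
    "derive_htn",
    "stratified_split",
    "SplitResult",
]


def impute_mode(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing cell by that SNP's modal observed value.

    Ties between equally frequent 0 and 1 resolve to 0 (the first mode).
    Raises if any SNP is entirely missing, naming the SNP.
    """
    values = genotypes.values.copy()
    obs = values != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = genotypes.snps["rsid"].iloc[int(np.flatnonzero(n_obs == 0)[0])]
        raise ValueError(f"SNP {bad} has no observed genotypes to impute from")
    ones = ((values == 1) & obs).sum(axis=0)
    mode = (ones * 2 > n_obs).astype(np.int8)  # strict majority of 1s
    rows, cols = np.nonzero(~obs)
    values[rows, cols] = mode[cols]
    return GenotypeMatrix(values=values, snps=genotypes.snps, subjects=genotypes.subjects)


def dominant_code(diploid_counts: np.ndarray) -> np.ndarray:
    """Collapse minor-allele counts {0,1,2} to carrier status {0,1}.

    Missing (-1) entries pass through unchanged.
    """
    counts = np.asarray(diploid_counts)
    ok = np.isin(counts, (0, 1, 2, MISSING))
    if not ok.all():
        bad = counts[~ok].ravel()[0]
        raise ValueError(f"diploid count {bad!r} outside {{0, 1, 2}}")
    out = np.where(counts == MISSING, MISSING, (counts > 0).astype(np.int8))
    return out.astype(np.int8)


def risk_ratio_filter(
    genotypes: GenotypeMatrix, trait: TraitVector
) -> GenotypeMatrix:
    """Keep only SNPs whose minor-allele risk ratio is at least 1.

    RR_s = P(T=1 | V_s=1) / P(T=1 | V_s=0).  SNPs with no non-carrier cases
    have RR = +inf and are retained (risk-allele semantics); SNPs with no
    carriers at all have an undefined ratio and are removed.
    """
    g = genotypes.values
    t = np.asarray(trait.htn, dtype=np.float64)
    if t.min() == t.max():
        raise ValueError("trait is constant; the risk ratio is undefined for every SNP")
    carriers = (g == 1).sum(axis=0)
    non_carriers = (g == 0).sum(axis=0)
    cases_carr = ((g == 1) & (t[:, None] == 1)).sum(axis=0)
    cases_non = ((g == 0) & (t[:, None] == 1)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = cases_carr / carriers
        p0 = cases_non / non_carriers
        rr = p1 / p0
    keep = np.zeros(genotypes.n_snps, dtype=bool)
    defined = carriers > 0
    zero_denom = defined & (non_carriers > 0) & (cases_non == 0) & (cases_carr > 0)
    keep |= zero_denom
    regular = defined & (cases_non > 0) & (non_carriers > 0)
    keep |= regular & (rr >= 1.0)
    # all subjects are carriers: p0 is 0/0; keep iff carriers contain cases
    all_carr = defined & (non_carriers == 0)
    keep |= all_carr & (cases_carr > 0)
    return genotypes.take_snps(np.flatnonzero(keep))


def dprime(snp_a: np.ndarray, snp_b: np.ndarray) -> float:
    """|D'| between two dominant-coded 0/1 columns.

    The columns are treated as binary alleles of a pseudo-haploid locus:
    with joint carrier frequency p11 and marginals pA, pB,
    D = p11 - pA*pB and D' = |D| / Dmax where Dmax is the largest |D|
    compatible with the marginals.  Symmetric in its arguments.
    """
    a = np.asarray(snp_a, dtype=np.float64)
    b = np.asarray(snp_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("LD is undefined for a constant column")
    p11 = (a * b).mean()
    d = p11 - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax == 0:
        return 0.0
    return float(abs(d) / dmax)


def ld_prune(
    genotypes: GenotypeMatrix,
    threshold: float = 0.2,
    window_bp: int = 500_000,
) -> GenotypeMatrix:
    """Greedy within-chromosome LD pruning at a |D'| threshold.

    SNPs are scanned left to right by position on each chromosome; whenever a
    new SNP forms a pair with an already-kept SNP closer than ``window_bp``
    and with |D'| above the threshold, the member of the pair with the lower
    MAF is dropped (ties drop the larger position).  Constant columns carry
    no LD information and are never pruned on LD grounds.  The operation is
    idempotent and the output preserves the input SNP order.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    snps = genotypes.snps
    mafs = snps["maf"].to_numpy()
    pos = snps["pos"].to_numpy()
    values = genotypes.values
    dropped = np.zeros(genotypes.n_snps, dtype=bool)
    constant = values.min(axis=0) == values.max(axis=0)
    for _, idx in snps.groupby("chrom", sort=False).groups.items():
        order = np.asarray(idx)[np.argsort(pos[idx], kind="stable")]
        kept: list[int] = []
        for j in order:
            if constant[j]:
                kept.append(j)
                continue
            for i in list(kept):
                if constant[i] or abs(pos[j] - pos[i]) >= window_bp:
                    continue
                if dprime(values[:, i], values[:, j]) > threshold:
                    # drop the lower-MAF SNP; tie -> larger position
                    if (mafs[i], -pos[i]) < (mafs[j], -pos[j]):
                        dropped[i] = True
                        kept.remove(i)
                    else:
                        dropped[j] = True
                        break
            if not dropped[j]:
                kept.append(j)
    return genotypes.take_snps(np.flatnonzero(~dropped))


def derive_htn(
    sbp: np.ndarray, dbp: np.ndarray, meds: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hypertension status with the medication adjustment.

    Medicated subjects get +10 mmHg SBP and +5 mmHg DBP; HTN = 1 iff the
    adjusted SBP >= 140 or adjusted DBP >= 90 or the subject is medicated.
    Returns (adjusted_sbp, adjusted_dbp, htn).  Missing blood pressure is
    tolerated only for medicated subjects (whose status is 1 regardless).
    """
    sbp = np.asarray(sbp, dtype=np.float64)
    dbp = np.asarray(dbp, dtype=np.float64)
    meds = np.asarray(meds)
    if not np.isin(meds, (0, 1)).all():
        raise ValueError("medication flag must be binary 0/1")
    missing_bp = np.isnan(sbp) | np.isnan(dbp)
    if (missing_bp & (meds == 0)).any():
        raise ValueError("missing blood pressure for an unmedicated subject")
    adj_sbp = sbp + 10.0 * meds
    adj_dbp = dbp + 5.0 * meds
    with np.errstate(invalid="ignore"):
        htn = ((adj_sbp >= 140) | (adj_dbp >= 90) | (meds == 1)).astype(np.int8)
    return adj_sbp, adj_dbp, htn


@dataclass
class SplitResult:
    """Stratified train/test partition of the subject ids."""

    train: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValueError("train and test sets overlap")


def stratified_split(
    subjects: np.ndarray,
    trait: TraitVector,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitResult:
    """Split cases and controls independently at ``train_fraction``.

    Each stratum contributes ``floor(train_fraction * n_stratum)`` subjects
    to the training set; the split is deterministic under ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    subjects = np.asarray(subjects)
    if len(subjects) != trait.n_subjects:
        raise ValueError("subjects and trait must align")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for label in (0, 1):
        stratum = np.flatnonzero(trait.htn == label)
        if len(stratum) < 2:
            raise ValueError(f"stratum htn={label} has fewer than 2 subjects")
        perm = rng.permutation(stratum)
        n_train = int(np.floor(train_fraction * len(stratum)))
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return SplitResult(train=subjects[train], test=subjects[test], seed=seed)
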