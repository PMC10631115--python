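"""Shared in-memory containers: genotype matrix, trait vector, patient explanation.

Genotypes are dominant-coded throughout the package: 0 = no copy of the minor
(risk) allele, 1 = one or two copies.  Missing values (pre-imputation only) are
encoded as -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: required per-SNP metadata columns
SNP_META_COLS = ("rsid", "chrom", "pos", "maf")


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs dominant-coded genotype matrix with SNP metadata.

    Parameters
    ----------
    values
        int8 array of shape ``(n_subjects, n_snps)`` with entries in
        ``{0, 1}`` (or ``-1`` for missing, before imputation).
    snps
        DataFrame with one row per SNP and columns ``rsid`` (str), ``chrom``
        (str), ``pos`` (int, base pairs) and ``maf`` (float in [0, 0.5]).
    subjects
        Array of subject identifiers, one per row of ``values``.
    """

    values: np.ndarray
    snps: pd.DataFrame
    subjects: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D subjects x SNPs array")
        self.subjects = np.asarray(self.subjects)
        if len(self.subjects) != self.values.shape[0]:
            raise ValueError("subject ids do not match the number of genotype rows")
        missing_cols = set(SNP_META_COLS) - set(self.snps.columns)
        if missing_cols:
            raise ValueError(f"snp metadata is missing columns: {sorted(missing_cols)}")
        if len(self.snps) != self.values.shape[1]:
            raise ValueError("snp metadata does not match the number of genotype columns")
        bad = ~np.isin(self.values, (0, 1, MISSING))
        if bad.any():
            raise ValueError("genotype values must be 0, 1 or -1 (missing)")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool((self.values == MISSING).any())

    def carrier_freq(self) -> np.ndarray:
        """Observed carrier (value 1) frequency per SNP, ignoring missing cells."""
        obs = self.values != MISSING
        carriers = (self.values == 1).sum(axis=0)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return carriers / n_obs

    def estimated_maf(self) -> np.ndarray:
        """MAF re-estimated from dominant-coded data.

        Under Hardy-Weinberg the carrier frequency is ``c = 1 - (1 - m)^2``,
        so ``m = 1 - sqrt(1 - c)``.  This keeps MAF comparable to values
        computed from diploid genotypes.
        """
        c = np.clip(self.carrier_freq(), 0.0, 1.0)
        return 1.0 - np.sqrt(1.0 - c)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            values=self.values[:, index],
            snps=self.snps.iloc[index].reset_index(drop=True),
            subjects=self.subjects,
        )

    def take_subjects(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            values=self.values[index, :],
            snps=self.snps,
            subjects=self.subjects[index],
        )


@dataclass
class TraitVector:
    """Per-subject binary trait with optional raw blood-pressure columns.

    ``htn`` is the binary trait (1 = affected).  ``sbp``/``dbp`` are systolic /
    diastolic blood pressure in mmHg and ``meds`` the antihypertensive
    medication flag; they are present only when the trait was derived from raw
    phenotype data.
    """

    htn: np.ndarray
    subjects: np.ndarray
    sbp: np.ndarray | None = None
    dbp: np.ndarray | None = None
    meds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.htn = np.asarray(self.htn, dtype=np.int8)
        self.subjects = np.asarray(self.subjects)
        if len(self.subjects) != len(self.htn):
            raise ValueError("subject ids do not match trait length")
        if not np.isin(self.htn, (0, 1)).all():
            raise ValueError("trait values must be binary 0/1")

    @property
    def n_subjects(self) -> int:
        return len(self.htn)

    @property
    def n_cases(self) -> int:
        return int(self.htn.sum())

    def take(self, index: np.ndarray) -> "TraitVector":
        index = np.asarray(index)

        def _sub(a: np.ndarray | None) -> np.ndarray | None:
            return None if a is None else np.asarray(a)[index]

        return TraitVector(
            htn=self.htn[index],
            subjects=self.subjects[index],
            sbp=_sub(self.sbp),
            dbp=_sub(self.dbp),
            meds=_sub(self.meds),
        )


@dataclass
class PatientExplanation:
    """Individualized posteriors for one patient.

    ``candidates`` are the indices (into the score table) of the SNPs the
    patient carries; ``posteriors`` the matching individualized posterior
    probabilities P(V_s^h -> T_i^h | D), which sum to 1 over the candidates;
    ``topk`` the candidate indices ordered by decreasing posterior (ties
    broken by smaller SNP index).
    """

    patient: object
    candidates: np.ndarray
    posteriors: np.ndarray
    topk: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.candidates = np.asarray(self.candidates)
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        if self.candidates.shape != self.posteriors.shape:
            raise ValueError("candidates and posteriors must align")
        if self.topk is None:
            # stable sort on -posterior keeps the smallest index first on ties
            order = np.argsort(-self.posteriors, kind="stable")
            self.topk = self.candidates[order]

    @property
    def top1(self) -> int:
        return int(self.topk[0])

    @property
    def top1_posterior(self) -> float:
        best = np.flatnonzero(self.candidates == self.topk[0])[0]
        return float(self.posteriors[best])
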