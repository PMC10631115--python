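"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from ibi.types import GenotypeMatrix, TraitVector


# ---------------------------------------------------------------------------
# independent oracles (never call package scoring code)
# ---------------------------------------------------------------------------

def log_rising(a: float, n: int) -> float:
    """log Gamma(a + n) / Gamma(a) as an explicit product — no lgamma."""
    return sum(math.log(a + i) for i in range(n))


def bdeu_oracle(n_jk, ess: float, q_model: int) -> float:
    """Direct gamma-ratio-product evaluation of the BDeu log marginal."""
    alpha = ess / (q_model * 2)
    total = 0.0
    for row in np.atleast_2d(n_jk):
        n0, n1 = int(row[0]), int(row[1])
        total += log_rising(alpha, n1) + log_rising(alpha, n0)
        total -= log_rising(2 * alpha, n1 + n0)
    return total


def one_parent_oracle(parent, trait, ess: float = 1.0) -> float:
    """BDeu score of V -> T on a full dataset via the product oracle."""
    parent = np.asarray(parent)
    trait = np.asarray(trait)
    rows = []
    for j in (0, 1):
        sel = parent == j
        rows.append([int(((trait == 0) & sel).sum()), int(((trait == 1) & sel).sum())])
    return bdeu_oracle(rows, ess, q_model=2)


def restricted_oracle(parent, trait, mask, ess: float = 1.0) -> float:
    """BDeu score of V -> T restricted to a subpopulation (q_model stays 2)."""
    parent = np.asarray(parent)[mask]
    trait = np.asarray(trait)[mask]
    rows = []
    for j in (0, 1):
        sel = parent == j
        rows.append([int(((trait == 0) & sel).sum()), int(((trait == 1) & sel).sum())])
    return bdeu_oracle(rows, ess, q_model=2)


def fisher_oracle(table) -> float:
    """Two-sided Fisher p-value by explicit hypergeometric enumeration."""
    from scipy import stats

    t = np.asarray(table, dtype=np.int64)
    n = int(t.sum())
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    ks = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(ks, n, c1, r1)
    observed = pmf[ks == t[0, 0]][0]
    return float(min(pmf[pmf <= observed * (1 + 1e-9)].sum(), 1.0))


def auroc_oracle(scores, labels) -> float:
    """Exhaustive case-control pair counting, ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# small-data builders
# ---------------------------------------------------------------------------

def make_genotypes(values, chrom=None, pos=None, maf=None) -> GenotypeMatrix:
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    snps = pd.DataFrame(
        {
            "rsid": [f"snp{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(m) * 1000,
            "maf": maf if maf is not None else np.full(m, 0.2),
        }
    )
    return GenotypeMatrix(values=values, snps=snps, subjects=np.arange(n).astype(str))


def make_trait(htn) -> TraitVector:
    htn = np.asarray(htn, dtype=np.int8)
    return TraitVector(htn=htn, subjects=np.arange(len(htn)).astype(str))


@pytest.fixture(scope="session")
def ab_results():
    """The ten-seed A/B benchmark, shared by the acceptance tests."""
    from ibi.benchmarks import run_ab_seeds

    return run_ab_seeds(range(1, 11))
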