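"""BDeu marginal likelihood for a binary trait node with zero or one binary parent.

The Bayesian Dirichlet equivalent uniform (BDeu) score is the closed-form log
marginal likelihood of discrete data under a Dirichlet-multinomial model whose
prior pseudo-counts are spread uniformly over the cells of the conditional
probability table: with equivalent sample size ``ess``, ``q`` parent
configurations and ``r`` child states, every cell receives ``ess / (q * r)``.

For a binary trait (r = 2) and at most one binary parent (q = 1 or 2) the
score is

    sum_j [ lnG(a_j) - lnG(a_j + N_j) + sum_k ( lnG(a_jk + N_jk) - lnG(a_jk) ) ]

with ``a_jk = ess / (q * r)``, ``a_j = sum_k a_jk`` and ``N_jk`` the count of
trait value ``k`` under parent configuration ``j``.  Everything is computed in
log space with ``scipy.special.gammaln``; raw gamma ratios are never formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "BdeuParams",
    "CountTable",
    "log_marglik",
    "count_one_parent",
    "config_logscore",
]


@dataclass(frozen=True)
class BdeuParams:
    """BDeu prior precision (equivalent sample size); must be positive."""

    ess: float = 1.0

    def __post_init__(self) -> None:
        if not self.ess > 0:
            raise ValueError("equivalent sample size must be > 0")


@dataclass
class CountTable:
    """Counts ``n_jk`` of trait value k under parent configuration j.

    ``n_jk`` has shape ``(q, 2)`` with q = 1 (no parent) or 2 (one binary
    parent).  ``q_model`` is the number of parent configurations of the model
    being scored; it defaults to the number of rows but may exceed it when the
    table is restricted to a subpopulation in which only some configurations
    occur (the per-configuration prior still uses the full model's q).
    """

    n_jk: np.ndarray
    q_model: int | None = None

    def __post_init__(self) -> None:
        self.n_jk = np.asarray(self.n_jk, dtype=np.int64)
        if self.n_jk.ndim != 2 or self.n_jk.shape[1] != 2:
            raise ValueError("count table must have shape (q, 2)")
        if (self.n_jk < 0).any():
            raise ValueError("counts must be non-negative")
        if self.q_model is None:
            self.q_model = self.n_jk.shape[0]
        if self.q_model < self.n_jk.shape[0]:
            raise ValueError("q_model cannot be smaller than the observed configurations")

    @property
    def total(self) -> int:
        return int(self.n_jk.sum())


def config_logscore(n1, n0, alpha: float):
    """Log BDeu contribution of a single parent configuration.

    ``n1``/``n0`` are the trait = 1 / trait = 0 counts under that
    configuration (scalars or broadcastable arrays) and ``alpha`` the
    per-cell Dirichlet pseudo-count ``ess / (q * r)``.  An empty
    configuration contributes exactly 0.
    """
    n1 = np.asarray(n1, dtype=np.float64)
    n0 = np.asarray(n0, dtype=np.float64)
    a_j = 2.0 * alpha
    return (
        gammaln(a_j)
        - gammaln(a_j + n1 + n0)
        + gammaln(alpha + n1)
        - gammaln(alpha)
        + gammaln(alpha + n0)
        - gammaln(alpha)
    )


def log_marglik(counts: CountTable, params: BdeuParams = BdeuParams()) -> float:
    """Natural-log BDeu marginal likelihood of a count table.

    The all-zero table scores exactly 0 (the marginal likelihood of no data
    is 1).  Finite for counts up to at least 1e6 thanks to the log-gamma
    formulation.
    """
    alpha = params.ess / (counts.q_model * 2.0)
    return float(
        np.sum(config_logscore(counts.n_jk[:, 1], counts.n_jk[:, 0], alpha))
    )


def count_one_parent(
    parent: np.ndarray,
    trait: np.ndarray,
    mask: np.ndarray | None = None,
) -> CountTable:
    """Tabulate ``n_jk = |{i in mask : parent_i = j, trait_i = k}|``.

    ``mask`` selects a subpopulation (boolean or index array); the default is
    the full cohort.  The returned table has both parent configurations and
    ``q_model = 2``.
    """
    parent = np.asarray(parent)
    trait = np.asarray(trait)
    if parent.shape != trait.shape:
        raise ValueError("parent and trait vectors must have equal length")
    if mask is not None:
        parent = parent[mask]
        trait = trait[mask]
    n_jk = np.zeros((2, 2), dtype=np.int64)
    for j in (0, 1):
        sel = parent == j
        n_jk[j, 1] = int(np.count_nonzero(trait[sel] == 1))
        n_jk[j, 0] = int(np.count_nonzero(sel) - n_jk[j, 1])
    return CountTable(n_jk, q_model=2)
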