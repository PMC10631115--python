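"""Information gain of single-variant vs paired-variant trait explanations.

All quantities are plug-in Shannon entropies in bits.  The paired information
gain defaults to the three-cell partition that matches the individualized
model's generative story — ``V_s`` explains its carriers, ``V_r`` the rest —
i.e. the cells {V_s=1}, {V_s=0, V_r=1}, {V_s=0, V_r=0}.  The standard
four-cell joint conditioning H(T) - H(T | V_s, V_r) is available as an
option; being a refinement it is always at least as large.
"""

from __future__ import annotations

import numpy as np

__all__ = ["entropy", "info_gain_single", "info_gain_pair"]


def entropy(labels: np.ndarray) -> float:
    """Plug-in Shannon entropy of a 0/1 vector, in bits (0*log 0 = 0)."""
    x = np.asarray(labels)
    if x.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    p = np.mean(x == 1)
    return float(_h2(p))


def _h2(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * np.log2(p) - (1 - p) * np.log2(1 - p)


def _partition_ig(trait: np.ndarray, cells: list[np.ndarray]) -> float:
    n = len(trait)
    h = entropy(trait)
    cond = 0.0
    for cell in cells:
        k = int(cell.sum())
        if k:
            cond += (k / n) * _h2(float(np.mean(trait[cell] == 1)))
    return float(h - cond)


def info_gain_single(snp: np.ndarray, trait: np.ndarray) -> float:
    """IG(V; T) = H(T) - sum_j (n_j/n) H(T | V=j), in bits."""
    v = np.asarray(snp)
    t = np.asarray(trait)
    if v.shape != t.shape:
        raise ValueError("vectors must have equal length")
    return _partition_ig(t, [v == 1, v == 0])


def info_gain_pair(
    snp_s: np.ndarray,
    snp_r: np.ndarray,
    trait: np.ndarray,
    four_cell: bool = False,
) -> float:
    """IG(V_s, V_r; T) under the three-cell partition (default) or the
    standard four-cell joint conditioning."""
    s = np.asarray(snp_s)
    r = np.asarray(snp_r)
    t = np.asarray(trait)
    if not (s.shape == r.shape == t.shape):
        raise ValueError("vectors must have equal length")
    if four_cell:
        cells = [
            (s == 1) & (r == 1),
            (s == 1) & (r == 0),
            (s == 0) & (r == 1),
            (s == 0) & (r == 0),
        ]
    else:
        cells = [s == 1, (s == 0) & (r == 1), (s == 0) & (r == 0)]
    return _partition_ig(t, cells)
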