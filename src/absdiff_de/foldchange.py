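"""Fold-change computation and shrinkage.

The log2 fold change of gene i can be written purely in terms of the
larger compensated group sum c_i and the absolute difference D_i:

    |FC_i| = log2( c_i / (c_i - D_i) ),

signed by which condition is larger. Three variants are emitted:

* ``fc_raw``  — the formula above on the observed (c_i, D_i);
* ``fc_expr`` — the same with the pseudocount-moderated c_hat_i, which
  attenuates the inflated fold changes of low-count genes;
* ``fc_full`` — additionally replaces D_i by the NB quantile D_hat_i
  whose upper-tail probability under the common dispersion r0 equals
  the gene's p-value, shrinking genes whose own dispersion exceeds the
  common one. Because the p-values themselves are untouched, this step
  never changes which genes are called significant.

Each step only attenuates: |fc_full| <= |fc_expr| <= |fc_raw|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core_test import GeneStats, ModelGlobals

__all__ = [
    "FoldChangeSet",
    "fc_raw",
    "nb_upper_tail_quantile",
    "fc_shrink_dispersion",
    "compute_foldchanges",
]


def _signed_log2_ratio(c: np.ndarray, d: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """sign * log2(c / (c - d)); 0 where d = 0, +/-inf where c <= d."""
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    sign = np.asarray(sign, dtype=float)
    out = np.zeros_like(c)
    active = d > 0
    denom = c - d
    exclusive = active & (denom <= 0)
    finite = active & (denom > 0)
    out[finite] = np.log2(c[finite] / denom[finite])
    out[exclusive] = np.inf
    return sign * out


def fc_raw(c, d, sign) -> np.ndarray:
    """Raw signed log2 fold change from the observed (c, D).

    Exclusive expression (c = D) yields an infinite sentinel; the
    expression-moderated variant is always finite because c_hat > D.
    """
    return _signed_log2_ratio(c, d, sign)


def nb_upper_tail_quantile(p, m, r) -> np.ndarray:
    """Smallest integer d with P(X >= d) <= p under NB(mean m, size r).

    The inverse of the upper-tail p-value at the same parameterization,
    so quantile(pvalue(D)) round-trips to D wherever the pmf is positive.
    p >= 1 maps to 0.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    m = np.broadcast_to(np.asarray(m, dtype=float), p.shape).copy()
    r = np.broadcast_to(np.asarray(r, dtype=float), p.shape).copy()
    prob = r / (r + m)
    # isf gives (approximately) the smallest k with sf(k) <= p; refine to be exact
    k = np.asarray(sps.nbinom.isf(p, r, prob), dtype=float)
    k = np.where(np.isfinite(k), k, -1.0)
    k = np.maximum(k, -1.0)
    for _ in range(64):  # boundary refinement; converges in 1-2 steps
        too_high = sps.nbinom.sf(k, r, prob) > p
        if not too_high.any():
            break
        k = k + too_high
    for _ in range(64):
        can_lower = (k >= 0) & (sps.nbinom.sf(k - 1, r, prob) <= p)
        if not can_lower.any():
            break
        k = k - can_lower
    return (k + 1).astype(np.int64)


def fc_shrink_dispersion(
    p: np.ndarray,
    m_hat: np.ndarray,
    r_hat: np.ndarray,
    r0: float,
    d: np.ndarray,
    c_hat: np.ndarray,
    sign: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Dispersion-moderated statistic D_hat and the fully shrunk fold change.

    Genes whose size r_hat falls below the common size r0 (i.e. whose
    dispersion exceeds the common one) get D_hat from the NB upper-tail
    quantile of their p-value at (m_hat, r0), capped at the observed D
    so moderation can only attenuate; all other genes keep D_hat = D.
    """
    p = np.asarray(p, dtype=float)
    d = np.asarray(d)
    d_hat = np.asarray(d, dtype=np.int64).copy()
    moderate = np.asarray(r_hat, dtype=float) < r0
    if moderate.any():
        q = nb_upper_tail_quantile(p[moderate], np.asarray(m_hat, dtype=float)[moderate], r0)
        d_hat[moderate] = np.minimum(q, d_hat[moderate])
    return d_hat, _signed_log2_ratio(c_hat, d_hat, sign)


@dataclass
class FoldChangeSet:
    """The three log2 fold-change variants plus the moderated statistic."""

    raw: np.ndarray
    expr: np.ndarray
    full: np.ndarray
    d_hat: np.ndarray
    sign: np.ndarray


def compute_foldchanges(
    stats: GeneStats, globs: ModelGlobals, pvalues: np.ndarray
) -> FoldChangeSet:
    """All three fold-change variants for a fitted gene-statistics set."""
    raw = fc_raw(stats.c, stats.d, stats.sign)
    expr = _signed_log2_ratio(stats.c_hat, stats.d, stats.sign)
    d_hat, full = fc_shrink_dispersion(
        pvalues, stats.m_hat, stats.r_hat, globs.r0, stats.d, stats.c_hat, stats.sign
    )
    return FoldChangeSet(raw=raw, expr=expr, full=full, d_hat=d_hat, sign=stats.sign)
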