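"""Outlier detection and replacement via a moderated MAD rule.

Read counts are roughly log-normal, so abnormally high counts are
flagged on the log scale with the median absolute deviation (MAD). At
RNA-Seq sample sizes the raw MAD of a gene's counts within a condition
is often zero, which would flag everything; the MAD is therefore shrunk
toward sigma0, the highest population standard deviation on the log
scale (dispersion is largest at the lowest expression, so sigma0 is the
fitted log-SD at mean count 1):

    M_hat^2 = (n * M^2 + n0 * sigma0^2) / (n + n0)

A count is an outlier when log(c+1) exceeds the within-condition median
by more than 2 * M_hat; it is replaced by exp(median + M_hat) - 1,
rounded, so a second pass flags nothing. Only upward outliers are ever
flagged — the rule is one-sided by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import CountMatrix
from .normalize import round_half_away

__all__ = [
    "MadParams",
    "OutlierReport",
    "moderated_mad",
    "estimate_sigma0",
    "mad_replace",
    "detect_and_replace",
]


@dataclass
class MadParams:
    """Parameters of the moderated-MAD rule.

    n0 is the pseudo-sample weight given to sigma0 (default 2); the
    cutoff multiplier is 2 MADs. sigma0 defaults to the data-driven
    estimate from :func:`estimate_sigma0` when built via ``from_matrix``.
    """

    n0: float = 2.0
    sigma0: float = 1.0
    multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.n0 < 0 or self.sigma0 < 0:
            raise ValueError("n0 and sigma0 must be non-negative")

    @classmethod
    def from_matrix(cls, cm: CountMatrix, n0: float = 2.0) -> "MadParams":
        return cls(n0=n0, sigma0=estimate_sigma0(cm))


def moderated_mad(log_counts: np.ndarray, params: MadParams) -> float:
    """Shrink the raw MAD of a log-count vector toward sigma0.

    The raw MAD is the unscaled median of absolute deviations from the
    median (no normal-consistency constant — it is blended directly with
    an SD).
    """
    x = np.asarray(log_counts, dtype=float)
    n = x.size
    if n < 1:
        raise ValueError("need at least one observation")
    m = np.median(np.abs(x - np.median(x)))
    denom = n + params.n0
    return float(np.sqrt((n * m**2 + params.n0 * params.sigma0**2) / denom))


def estimate_sigma0(cm: CountMatrix | np.ndarray) -> float:
    """Fitted log-scale SD at mean count 1 (the highest-dispersion regime).

    Per-gene SD of log(c+1) is regressed on the per-gene mean of
    log(c+1) with a lowess fit forced monotone non-increasing, and
    evaluated at log(2) (i.e. count 1). Degenerate fits fall back to the
    maximum observed per-gene log-scale SD.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else np.asarray(cm)
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples to estimate sigma0")
    logc = np.log(counts + 1.0)
    means = logc.mean(axis=1)
    sds = logc.std(axis=1, ddof=1)
    max_sd = float(sds.max()) if sds.size else 0.0
    if max_sd < 1e-12:  # all genes constant across samples
        return 0.0
    if means.size < 5 or np.ptp(means) == 0:
        return max_sd
    span = np.ptp(means)
    fitted = lowess(sds, means, frac=0.75, delta=0.01 * span, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    # enforce a non-increasing trend: dispersion decreases with expression
    ys = np.maximum.accumulate(ys[::-1])[::-1]
    val = float(np.interp(np.log(2.0), xs, ys))
    if not np.isfinite(val) or val <= 0:
        return max_sd
    return val


def mad_replace(
    counts: np.ndarray, groups: list[np.ndarray], params: MadParams
) -> tuple[np.ndarray, np.ndarray]:
    """Array-level moderated-MAD replacement within each column group.

    Returns ``(flags, replaced)`` where ``groups`` lists column-index
    arrays treated as independent conditions. Replacing an extreme
    value shrinks the group's MAD, which can expose a further
    borderline cell, so the rule is applied repeatedly until a pass
    changes nothing — making the operation idempotent. Flags accumulate
    over passes.
    """
    counts = np.asarray(counts).astype(np.int64).copy()
    flags = np.zeros(counts.shape, dtype=bool)
    for idx in groups:
        idx = np.asarray(idx)
        if idx.size < 2:
            continue  # a single observation never deviates from its own median
        n = idx.size
        while True:
            block = np.log(counts[:, idx] + 1.0)
            med = np.median(block, axis=1)
            raw_mad = np.median(np.abs(block - med[:, None]), axis=1)
            m_hat = np.sqrt((n * raw_mad**2 + params.n0 * params.sigma0**2) / (n + params.n0))
            over = block - med[:, None] - params.multiplier * m_hat[:, None] > 0
            if not over.any():
                break
            repl = np.maximum(round_half_away(np.exp(med + m_hat) - 1.0), 0.0)
            rows, cols = np.nonzero(over)
            changed = counts[rows, idx[cols]] != repl[rows].astype(np.int64)
            counts[rows, idx[cols]] = repl[rows].astype(np.int64)
            flags[rows, idx[cols]] = True
            if not changed.any():
                break  # degenerate: replacement reproduces the flagged value
    return flags, counts


def detect_and_replace(cm: CountMatrix, params: MadParams) -> "OutlierReport":
    """Flag and replace abnormally high counts per gene per condition.

    Cell (i, j) in condition g is flagged iff
    ``log(c_ij+1) - median_g(log(c_i.+1)) - 2*M_hat > 0`` and replaced by
    ``round(exp(median_g + M_hat) - 1)`` floored at 0.
    """
    idx_a, idx_b = cm.group_indices()
    flags, counts = mad_replace(cm.counts, [idx_a, idx_b], params)
    return OutlierReport(flags=flags, replaced_counts=cm.with_counts(counts))


@dataclass
class OutlierReport:
    """Boolean flags (genes x samples) plus the matrix after replacement."""

    flags: np.ndarray
    replaced_counts: CountMatrix

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())
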