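"""Library-size normalization of read-count matrices.

Sequencing depth varies between libraries, so raw counts are not
comparable across samples. Two per-sample scaling schemes are provided:

* upper-quartile (``quantile``): a sample's factor is proportional to the
  0.75 quantile of its nonzero counts;
* median-of-ratios (``geometric``): a sample's factor is the median over
  reference genes of the ratio between its count and the gene's
  geometric mean across samples.

Factors are rescaled to geometric mean 1 so average library depth is
preserved, and normalized counts are rounded back to integers because
the downstream count model consumes integer data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CountMatrix

__all__ = [
    "SizeFactors",
    "read_counts",
    "write_counts",
    "filter_all_zero",
    "size_factors_quantile",
    "size_factors_geometric",
    "apply_normalization",
    "round_half_away",
]


@dataclass
class SizeFactors:
    """Per-sample scaling factors with geometric mean 1."""

    factors: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.size and self.factors.min() <= 0:
            raise ValueError("size factors must be positive")


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to the nearest integer with halves away from zero."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _rescale_geomean(raw: np.ndarray) -> np.ndarray:
    raw = np.asarray(raw, dtype=float)
    return raw / np.exp(np.mean(np.log(raw)))


# ----------------------------------------------------------------------
# I/O


def _parse_design(design, sample_ids) -> dict[str, str]:
    if isinstance(design, dict):
        return {str(k): str(v) for k, v in design.items()}
    # sequence of labels positional in header order
    labels = [str(v) for v in design]
    if len(labels) != len(sample_ids):
        raise ValueError("positional design length does not match sample count")
    return dict(zip(sample_ids, labels))


def read_counts(path, design, paired: bool = False) -> CountMatrix:
    """Read a TSV/CSV count table (gene IDs in the first column).

    ``design`` is either a mapping ``sample -> condition`` or a sequence
    of condition labels in header order. Non-integer or negative cells
    are an error, as are duplicate gene IDs or design samples absent
    from the header.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dups}")
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise ValueError("count table contains non-numeric cells")
    sample_ids = [str(c) for c in df.columns]
    mapping = _parse_design(design, sample_ids)
    return CountMatrix(
        counts=values,
        gene_ids=[str(g) for g in df.index],
        sample_ids=sample_ids,
        design=mapping,
        paired=paired,
    )


def write_counts(cm: CountMatrix, path) -> None:
    """Write a count matrix in the same TSV/CSV layout ``read_counts`` expects."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    cm.to_frame().to_csv(path, sep=sep)


# ----------------------------------------------------------------------
# Filtering and factors


def filter_all_zero(cm: CountMatrix) -> CountMatrix:
    """Drop genes whose counts are zero in every sample (order preserved)."""
    keep = cm.counts.sum(axis=1) > 0
    return CountMatrix(
        counts=cm.counts[keep],
        gene_ids=[g for g, k in zip(cm.gene_ids, keep) if k],
        sample_ids=cm.sample_ids,
        design=cm.design,
        paired=cm.paired,
    )


def quantile_factors(counts: np.ndarray, q: float = 0.75) -> np.ndarray:
    """Raw per-sample factors: the q-th quantile of each sample's nonzero counts."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    counts = np.asarray(counts)
    raw = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        col = counts[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample column {j} has all-zero counts")
        raw[j] = np.quantile(nz, q)
    return raw


def size_factors_quantile(cm: CountMatrix, q: float = 0.75) -> SizeFactors:
    """Upper-quartile size factors (q-th quantile of nonzero counts)."""
    raw = quantile_factors(cm.counts, q)
    return SizeFactors(factors=_rescale_geomean(raw), method="quantile")


def geometric_factors(counts: np.ndarray) -> np.ndarray:
    """Raw median-of-ratios factors against all-positive reference genes."""
    counts = np.asarray(counts, dtype=float)
    ref = np.all(counts > 0, axis=1)
    if not ref.any():
        raise ValueError("no gene with all-positive counts to anchor the reference")
    logc = np.log(counts[ref])
    log_geomean = logc.mean(axis=1)
    return np.exp(np.median(logc - log_geomean[:, None], axis=0))


def size_factors_geometric(cm: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors against the per-gene geometric mean."""
    raw = geometric_factors(cm.counts)
    return SizeFactors(factors=_rescale_geomean(raw), method="geometric")


def apply_normalization(cm: CountMatrix, sf: SizeFactors) -> CountMatrix:
    """Scale each sample by its factor and round back to integer counts."""
    if len(sf.factors) != cm.n_samples:
        raise ValueError("size factors do not cover every sample")
    scaled = cm.counts / sf.factors[None, :]
    return cm.with_counts(round_half_away(scaled).astype(np.int64))
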