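"""Count-matrix container for two-condition RNA-Seq experiments.

The central data structure is a genes x samples table of non-negative
integer read counts together with a design mapping each sample to one of
exactly two condition labels. Samples may optionally be paired, in which
case the k-th sample of one condition is matched with the k-th sample of
the other (in design order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """A genes x samples integer count table with a two-group design.

    Parameters
    ----------
    counts
        Array of shape ``(n_genes, n_samples)``; non-negative integers.
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    design
        Mapping ``sample_id -> condition label``; exactly two distinct
        labels, each with at least one sample.
    paired
        If true, conditions must have equal size and the samples are
        paired in design order (k-th of A with k-th of B).
    """

    counts: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    design: dict[str, str]
    paired: bool = False

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples array")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.round(counts)):
                raise ValueError("counts must be integral")
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != counts.shape[0]:
            raise ValueError("gene_ids length does not match counts")
        if len(self.sample_ids) != counts.shape[1]:
            raise ValueError("sample_ids length does not match counts")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")

        missing = [s for s in self.sample_ids if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        absent = [s for s in self.design if s not in self.sample_ids]
        if absent:
            raise ValueError(f"design references absent samples: {absent}")

        labels = sorted(set(self.design.values()))
        if len(labels) != 2:
            raise ValueError(f"design must have exactly two conditions, got {labels}")
        sizes = [sum(1 for s in self.sample_ids if self.design[s] == lab) for lab in labels]
        if min(sizes) < 1:
            raise ValueError("both conditions need at least one sample")
        if self.paired and sizes[0] != sizes[1]:
            raise ValueError("paired design requires equal group sizes")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def conditions(self) -> tuple[str, str]:
        """The two condition labels in sorted order (reference first)."""
        labels = sorted(set(self.design.values()))
        return labels[0], labels[1]

    def group_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of the two conditions, in sorted label order."""
        lab_a, lab_b = self.conditions
        idx_a = np.array([j for j, s in enumerate(self.sample_ids) if self.design[s] == lab_a])
        idx_b = np.array([j for j, s in enumerate(self.sample_ids) if self.design[s] == lab_b])
        return idx_a, idx_b

    def labels(self) -> np.ndarray:
        """Per-sample condition labels, aligned with ``sample_ids``."""
        return np.array([self.design[s] for s in self.sample_ids])

    def with_counts(self, counts: np.ndarray) -> "CountMatrix":
        """A copy of this matrix with a new count table of identical shape."""
        return replace(self, counts=counts)

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by gene with one column per sample."""
        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        return df
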