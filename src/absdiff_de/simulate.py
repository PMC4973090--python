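"""Synthetic two-group count matrices with known ground truth.

The generator emulates the standard benchmark regime for count-based
differential expression: per-gene baseline means drawn log-normally,
negative binomial counts with a quadratic mean-variance structure
(dispersion decreasing in the mean, with lognormal gene-to-gene noise),
an optional block of up- and down-regulated genes with effect sizes
|log2FC| = 1.5 + Exp(1), and optional 5-10x multiplicative outliers
injected into genes selected with probability 0.05.

Defaults follow the benchmark layout: 12,500 genes, replicate group
sizes of 2, 5 or 10, and for DE settings 10 % of genes split evenly
into 625 up- and 625 down-regulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .matrix import CountMatrix
from .normalize import write_counts

__all__ = ["SimConfig", "SimTruth", "simulate_counts", "write_fixture", "read_truth"]


def _default_dispersion(means: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dispersion decreasing in the mean plus lognormal noise.

    phi(mu) = 0.04 + 0.8/mu, scaled by exp(N(0, 0.3)): variance
    mu + phi mu^2 is quadratic in the mean with the highest dispersion
    at the lowest expression.
    """
    base = 0.04 + 0.8 / np.maximum(means, 1.0)
    return base * rng.lognormal(0.0, 0.3, size=means.shape)


@dataclass
class SimConfig:
    """Configuration of one simulated two-group experiment.

    Attributes
    ----------
    n_genes, n_per_group
        Matrix dimensions; group sizes of 2, 5 and 10 match the
        benchmark settings but any value >= 1 is accepted.
    n_de_up, n_de_down
        Number of up-/down-regulated genes (0 for a null dataset).
    log2fc_location, log2fc_scale
        Effect sizes are |log2FC| = location + Exponential(scale).
    mean_log_location, mean_log_scale
        Per-gene baseline means are lognormal with these natural-log
        parameters.
    dispersion_function
        Callable ``(means, rng) -> dispersions``; None uses the default
        decreasing-in-mean form. Returning 0 for a gene makes it
        Poisson.
    poisson_fraction
        Fraction of genes forced to dispersion 0 (Poisson), emulating
        the half-NB/half-Poisson setting.
    outlier_mode
        "none", "single_sample" or "random"; both active modes select
        genes with probability ``outlier_prob`` and multiply one count
        of each selected gene (in a randomly chosen sample) by a factor
        drawn uniformly from ``outlier_factor_range``.
    seed
        Seed for the generator; same seed, same dataset.
    """

    n_genes: int = 12500
    n_per_group: int = 5
    n_de_up: int = 625
    n_de_down: int = 625
    log2fc_location: float = 1.5
    log2fc_scale: float = 1.0
    mean_log_location: float = 6.0
    mean_log_scale: float = 1.5
    dispersion_function: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None
    poisson_fraction: float = 0.0
    outlier_mode: str = "none"
    outlier_prob: float = 0.05
    outlier_factor_range: tuple[float, float] = (5.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de_up + self.n_de_down > self.n_genes:
            raise ValueError("more DE genes than genes")
        if not 0 <= self.outlier_prob <= 1:
            raise ValueError("outlier_prob must be in [0, 1]")
        if self.outlier_factor_range[0] < 1:
            raise ValueError("outlier factors must be >= 1")
        if self.outlier_mode not in ("none", "single_sample", "random"):
            raise ValueError(f"unknown outlier_mode {self.outlier_mode!r}")
        if not 0 <= self.poisson_fraction <= 1:
            raise ValueError("poisson_fraction must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    de_labels: np.ndarray  # per gene: "up", "down" or "null"
    true_log2fc: np.ndarray
    outlier_cells: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_de(self) -> np.ndarray:
        return self.de_labels != "null"


def _draw_counts(
    rng: np.random.Generator, means: np.ndarray, dispersions: np.ndarray
) -> np.ndarray:
    """NB(mean, dispersion) draws; dispersion 0 degenerates to Poisson."""
    out = np.empty(means.shape, dtype=np.int64)
    pois = dispersions <= 0
    if pois.any():
        out[pois] = rng.poisson(means[pois])
    nb = ~pois
    if nb.any():
        size = 1.0 / dispersions[nb]
        prob = size / (size + means[nb])
        out[nb] = rng.negative_binomial(size, prob)
    return out


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw one dataset and its truth from a configuration.

    Group-B means of DE genes are scaled by 2^log2fc; counts are NB
    draws at the gene's mean and dispersion; outliers are injected
    afterwards and recorded as (gene, sample) cells. Deterministic
    under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    g, n = cfg.n_genes, cfg.n_per_group

    means = rng.lognormal(cfg.mean_log_location, cfg.mean_log_scale, size=g)
    disp_fn = cfg.dispersion_function or _default_dispersion
    dispersions = np.asarray(disp_fn(means, rng), dtype=float)
    if cfg.poisson_fraction > 0:
        pois = rng.random(g) < cfg.poisson_fraction
        dispersions[pois] = 0.0

    labels = np.full(g, "null", dtype=object)
    lfc = np.zeros(g)
    n_de = cfg.n_de_up + cfg.n_de_down
    if n_de:
        de_idx = rng.choice(g, size=n_de, replace=False)
        up, down = de_idx[: cfg.n_de_up], de_idx[cfg.n_de_up :]
        labels[up], labels[down] = "up", "down"
        mags = cfg.log2fc_location + rng.exponential(cfg.log2fc_scale, size=n_de)
        lfc[up] = mags[: cfg.n_de_up]
        lfc[down] = -mags[cfg.n_de_up :]

    mean_a = np.repeat(means[:, None], n, axis=1)
    mean_b = np.repeat((means * 2.0**lfc)[:, None], n, axis=1)
    disp = np.repeat(dispersions[:, None], n, axis=1)
    counts = np.concatenate(
        [_draw_counts(rng, mean_a, disp), _draw_counts(rng, mean_b, disp)], axis=1
    )

    outlier_cells: list[tuple[int, int]] = []
    if cfg.outlier_mode != "none" and cfg.outlier_prob > 0:
        hit = np.flatnonzero(rng.random(g) < cfg.outlier_prob)
        cols = rng.integers(0, 2 * n, size=hit.size)
        factors = rng.uniform(*cfg.outlier_factor_range, size=hit.size)
        counts[hit, cols] = np.round(counts[hit, cols] * factors).astype(np.int64)
        outlier_cells = list(zip(hit.tolist(), cols.tolist()))

    sample_ids = [f"A{k + 1}" for k in range(n)] + [f"B{k + 1}" for k in range(n)]
    design = {s: s[0] for s in sample_ids}
    cm = CountMatrix(
        counts=counts,
        gene_ids=[f"gene{i + 1:05d}" for i in range(g)],
        sample_ids=sample_ids,
        design=design,
    )
    truth = SimTruth(
        de_labels=np.asarray(labels, dtype=str),
        true_log2fc=lfc,
        outlier_cells=outlier_cells,
    )
    return cm, truth


# ----------------------------------------------------------------------
# Fixture I/O


def write_fixture(cm: CountMatrix, truth: SimTruth, directory) -> dict[str, Path]:
    """Write counts.tsv, design.tsv and truth.tsv; round-trip safe."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "design": directory / "design.tsv",
        "truth": directory / "truth.tsv",
    }
    write_counts(cm, paths["counts"])
    pd.DataFrame(
        {"sample_id": cm.sample_ids, "condition": [cm.design[s] for s in cm.sample_ids]}
    ).to_csv(paths["design"], sep="\t", index=False)
    outlier_samples = [[] for _ in range(cm.n_genes)]
    for i, j in truth.outlier_cells:
        outlier_samples[i].append(cm.sample_ids[j])
    pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "de_label": truth.de_labels,
            "true_log2fc": truth.true_log2fc,
            "outlier_samples": [";".join(s) for s in outlier_samples],
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_truth(path) -> pd.DataFrame:
    """Read a truth.tsv written by :func:`write_fixture`."""
    return pd.read_csv(path, sep="\t", dtype={"outlier_samples": str}, keep_default_na=False)
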