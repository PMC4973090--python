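"""scikit-learn style estimators for the absolute count-difference test.

The main entry point is :class:`AbsDiffDE`, which follows the sklearn
convention of ``X`` with shape ``(n_samples, n_features)`` — samples are
RNA-Seq libraries, features are genes — and ``y`` holding the two
condition labels. After ``fit`` the per-gene results live in trailing-
underscore attributes (``pvalues_``, ``padj_``, ``log2fc_full_``, ...),
and because the class implements the selector interface, ``transform``
reduces a matrix to the genes significant at the configured FDR, so the
test composes with sklearn pipelines.

Normalization and outlier replacement are also exposed as standalone
transformers (:class:`UpperQuartileScaler`, :class:`MedianOfRatiosScaler`,
:class:`ModeratedMADReplacer`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted, column_or_1d

from . import core_test, foldchange, normalize, outliers

__all__ = [
    "AbsDiffDE",
    "UpperQuartileScaler",
    "MedianOfRatiosScaler",
    "ModeratedMADReplacer",
]


def _validate_counts(X) -> np.ndarray:
    """Validate a samples x genes matrix of non-negative integral counts."""
    X = check_array(X, dtype=np.float64, ensure_min_samples=2)
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    if np.any(X != np.round(X)):
        raise ValueError("counts must be integral")
    return X


def _two_group_indices(y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = column_or_1d(np.asarray(y, dtype=object).astype(str))
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"exactly two condition labels required, got {classes.tolist()}")
    return classes, np.flatnonzero(y == classes[0]), np.flatnonzero(y == classes[1])


class AbsDiffDE(SelectorMixin, BaseEstimator):
    """Two-condition differential expression test on absolute count differences.

    The per-gene statistic is the absolute difference of read-count sums
    between conditions, tested against a moderated negative binomial
    null; see :mod:`absdiff_de.core_test` for the model. Fitting runs
    the full pipeline: size-factor normalization, moderated-MAD outlier
    replacement, moderation of the NB mean and size via the
    mean-variance trend, upper-tail p-values, BH adjustment and the
    three fold-change variants.

    Parameters
    ----------
    normalization : {"quantile", "geometric", "none"}, default "quantile"
        Size-factor scheme: upper-quartile of nonzero counts,
        median-of-ratios against per-gene geometric means, or none.
    quantile : float, default 0.75
        Quantile used by the ``"quantile"`` scheme.
    outlier_filter : bool, default True
        Replace abnormally high counts with the moderated-MAD rule
        before testing.
    mad_n0 : float, default 2.0
        Pseudo-sample weight shrinking per-gene MADs toward ``sigma0``.
    mad_sigma0 : float or None, default None
        Highest population log-scale SD; estimated from the data
        (fitted log-SD at mean count 1) when None.
    alpha : float or None, default None
        Experiment-wide coefficient of variation; estimated from
        log2-scale residual SDs when None.
    paired : bool, default False
        Treat the k-th sample of each condition (in order of
        appearance) as a pair and derive variances from the per-pair
        differences.
    trend_span : float, default 0.75
        Local-regression span for the mean-variance trend fit.
    fdr : float, default 0.05
        BH-adjusted p-value threshold used by the selector interface.

    Attributes
    ----------
    pvalues_, padj_ : ndarray of shape (n_genes,)
        Upper-tail NB p-values and BH-adjusted values.
    statistic_ : ndarray
        The absolute-difference statistic D per gene.
    log2fc_raw_, log2fc_expr_, log2fc_full_ : ndarray
        Raw, expression-moderated and dispersion-moderated log2 fold
        changes, oriented as second vs first sorted condition (positive
        = higher in the second).
    alpha_, theta_, v0_, beta_, r0_ : float
        Fitted moderation constants.
    size_factors_ : ndarray of shape (n_samples,)
        Per-sample scaling factors actually applied.
    sigma0_ : float
        MAD-shrinkage target used by the outlier step (0.0 if disabled).

    Examples
    --------
    >>> import numpy as np
    >>> from absdiff_de import AbsDiffDE
    >>> rng = np.random.default_rng(0)
    >>> X = rng.poisson(50, size=(6, 100))
    >>> y = ["A", "A", "A", "B", "B", "B"]
    >>> de = AbsDiffDE().fit(X, y)
    >>> de.padj_.shape
    (100,)
    """

    def __init__(
        self,
        normalization: str = "quantile",
        quantile: float = 0.75,
        outlier_filter: bool = True,
        mad_n0: float = 2.0,
        mad_sigma0: float | None = None,
        alpha: float | None = None,
        paired: bool = False,
        trend_span: float = 0.75,
        fdr: float = 0.05,
    ):
        self.normalization = normalization
        self.quantile = quantile
        self.outlier_filter = outlier_filter
        self.mad_n0 = mad_n0
        self.mad_sigma0 = mad_sigma0
        self.alpha = alpha
        self.paired = paired
        self.trend_span = trend_span
        self.fdr = fdr

    # ------------------------------------------------------------------
    def fit(self, X, y):
        """Run the test on a samples x genes count matrix.

        Parameters
        ----------
        X : array-like of shape (n_samples, n_genes)
            Non-negative integer read counts.
        y : array-like of shape (n_samples,)
            Condition label per sample (exactly two distinct labels).
        """
        X = _validate_counts(X)
        self.classes_, idx_a, idx_b = _two_group_indices(y)
        self.n_features_in_ = X.shape[1]
        counts = X.T.astype(np.int64)  # genes x samples internally

        # 1. library-size normalization
        if self.normalization == "quantile":
            raw = normalize.quantile_factors(counts, self.quantile)
        elif self.normalization == "geometric":
            raw = normalize.geometric_factors(counts)
        elif self.normalization == "none":
            raw = np.ones(counts.shape[1])
        else:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        factors = raw / np.exp(np.mean(np.log(raw)))
        self.size_factors_ = factors
        counts = normalize.round_half_away(counts / factors[None, :]).astype(np.int64)

        # 2. moderated-MAD outlier replacement, per gene per condition
        if self.outlier_filter:
            sigma0 = (
                outliers.estimate_sigma0(counts)
                if self.mad_sigma0 is None
                else float(self.mad_sigma0)
            )
            params = outliers.MadParams(n0=self.mad_n0, sigma0=sigma0)
            self.outlier_flags_, counts = outliers.mad_replace(counts, [idx_a, idx_b], params)
            self.sigma0_ = sigma0
        else:
            self.outlier_flags_ = np.zeros(counts.shape, dtype=bool)
            self.sigma0_ = 0.0

        # 3. moderated NB test on the absolute difference statistic
        stats, globs = core_test.compute_gene_stats(
            counts, idx_a, idx_b,
            paired=self.paired, alpha=self.alpha, trend_span=self.trend_span,
        )
        pvals = core_test.pvalue(stats.d, stats.m_hat, stats.r_hat)
        pvals = np.where(stats.mu > 0, pvals, 1.0)

        # 4. fold changes
        fcs = foldchange.compute_foldchanges(stats, globs, pvals)

        self.stats_ = stats
        self.globals_ = globs
        self.normalized_counts_ = counts
        self.statistic_ = stats.d
        self.pvalues_ = pvals
        self.padj_ = core_test.adjust_bh(pvals)
        self.log2fc_raw_ = fcs.raw
        self.log2fc_expr_ = fcs.expr
        self.log2fc_full_ = fcs.full
        self.d_hat_ = fcs.d_hat
        self.alpha_ = globs.alpha
        self.theta_ = globs.theta
        self.v0_ = globs.v0
        self.beta_ = globs.beta
        self.r0_ = globs.r0
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "padj_")
        return self.padj_ < self.fdr

    def results(self, gene_ids=None) -> pd.DataFrame:
        """Per-gene results table (means, D, p-values, fold changes)."""
        check_is_fitted(self, "padj_")
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(self.n_features_in_)]
        return core_test.TestResult(
            gene_ids=list(gene_ids),
            mean_a=self.stats_.mu_a,
            mean_b=self.stats_.mu_b,
            statistic=self.statistic_,
            pvalue=self.pvalues_,
            padj=self.padj_,
            log2fc_raw=self.log2fc_raw_,
            log2fc_expr=self.log2fc_expr_,
            log2fc_full=self.log2fc_full_,
            conditions=tuple(self.classes_),
        ).to_frame()

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        tags.input_tags.positive_only = True
        return tags


class UpperQuartileScaler(TransformerMixin, BaseEstimator):
    """Scale each sample (row) by the q-th quantile of its nonzero counts.

    Factors are rescaled to geometric mean 1 within the transformed
    batch and scaled counts are rounded back to integers. The scaling
    is per-sample, hence stateless: factors are recomputed for the rows
    being transformed; ``fit`` records the factors of the fitted batch
    in ``size_factors_`` for inspection.
    """

    def __init__(self, q: float = 0.75):
        self.q = q

    def fit(self, X, y=None):
        X = _validate_counts(X)
        self.n_features_in_ = X.shape[1]
        self.size_factors_ = self._factors(X)
        return self

    def _factors(self, X) -> np.ndarray:
        raw = normalize.quantile_factors(X.T, self.q)
        return raw / np.exp(np.mean(np.log(raw)))

    def transform(self, X):
        check_is_fitted(self, "size_factors_")
        X = _validate_counts(X)
        factors = self._factors(X)
        return normalize.round_half_away(X / factors[:, None]).astype(np.int64)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.positive_only = True
        return tags


class MedianOfRatiosScaler(TransformerMixin, BaseEstimator):
    """Median-of-ratios scaling against a fitted per-gene reference.

    ``fit`` stores the log geometric mean of every gene expressed in all
    fitted samples; ``transform`` scales each row by the median ratio of
    its counts to that reference (rescaled to geometric mean 1 within
    the batch) and rounds back to integers.
    """

    def fit(self, X, y=None):
        X = _validate_counts(X)
        self.n_features_in_ = X.shape[1]
        counts = X.T
        ref = np.all(counts > 0, axis=1)
        if not ref.any():
            raise ValueError("no gene with all-positive counts to anchor the reference")
        self.reference_mask_ = ref
        self.log_geomeans_ = np.log(counts[ref].astype(float)).mean(axis=1)
        return self

    def transform(self, X):
        check_is_fitted(self, "log_geomeans_")
        X = _validate_counts(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("gene count differs from fit")
        ref = X[:, self.reference_mask_].astype(float)
        ref[ref == 0] = np.nan  # genes silent in a new sample drop out of its median
        with np.errstate(invalid="ignore"):
            logc = np.log(ref)
            raw = np.exp(np.nanmedian(logc - self.log_geomeans_[None, :], axis=1))
        if not np.all(np.isfinite(raw)):
            raise ValueError("a sample shares no expressed gene with the reference")
        factors = raw / np.exp(np.mean(np.log(raw)))
        return normalize.round_half_away(X / factors[:, None]).astype(np.int64)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.positive_only = True
        return tags


class ModeratedMADReplacer(TransformerMixin, BaseEstimator):
    """Replace abnormally high counts with the moderated-MAD rule.

    When ``fit`` receives condition labels ``y`` the replacement at
    ``transform`` time is applied per condition (requiring the same
    sample layout); without labels all samples form one group. The
    shrinkage target ``sigma0`` is estimated from the fitted data
    unless given.
    """

    def __init__(self, n0: float = 2.0, sigma0: float | None = None):
        self.n0 = n0
        self.sigma0 = sigma0

    def fit(self, X, y=None):
        X = _validate_counts(X)
        self.n_features_in_ = X.shape[1]
        self.sigma0_ = (
            outliers.estimate_sigma0(X.T.astype(np.int64))
            if self.sigma0 is None
            else float(self.sigma0)
        )
        self.groups_ = None if y is None else column_or_1d(np.asarray(y).astype(str))
        return self

    def transform(self, X):
        check_is_fitted(self, "sigma0_")
        X = _validate_counts(X)
        if self.groups_ is not None and len(self.groups_) == X.shape[0]:
            groups = [np.flatnonzero(self.groups_ == g) for g in np.unique(self.groups_)]
        else:
            groups = [np.arange(X.shape[0])]
        params = outliers.MadParams(n0=self.n0, sigma0=self.sigma0_)
        flags, replaced = outliers.mad_replace(X.T.astype(np.int64), groups, params)
        self.flags_ = flags.T
        return replaced.T

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.positive_only = True
        return tags
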