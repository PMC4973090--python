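"""The absolute count-difference test.

The test statistic for gene i is the absolute difference of read-count
sums between the two conditions,

    D_i = | sum_{j in A} c_ij - sum_{j in B} c_ij |,

modelled as a negative binomial NB(m_i, r_i) with mean m_i and size r_i.
Both parameters are moderated before testing:

* the mean m_i = alpha * c_i is the larger group sum scaled by the
  experiment-wide coefficient of variation alpha, inflated by a
  pseudocount derived from the smoothed mean-variance trend (counts are
  more uncertain at low expression) and a noise term epsilon;
* the size r_i is the inverse pooled dispersion, penalized by a basic
  dispersion factor v0 (a quantile of the positive dispersions keyed to
  the fraction of underdispersed genes) and by the trend dispersion
  divided by the sample size.

The p-value is the NB upper tail P(X >= D_i); large absolute
differences relative to the moderated null are evidence of differential
expression. Benjamini-Hochberg step-up adjustment controls the FDR.

With unequal group sizes the smaller group's sum is compensated by
appending pseudo-replicates equal to its own mean, so D_i does not
favour the larger group. In paired designs the pooled within-group
variance s2_A + s2_B is replaced throughout by the sample variance of
the per-pair differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix
from .normalize import round_half_away

__all__ = [
    "GeneStats",
    "ModelGlobals",
    "TestResult",
    "group_sums_with_compensation",
    "pooled_dispersion",
    "fit_mean_variance_trend",
    "smoothed_variance",
    "pseudocount_moderation",
    "penalized_dispersion",
    "estimate_alpha",
    "moderated_mean",
    "pvalue",
    "adjust_bh",
    "compute_gene_stats",
    "run_test",
]

V_BAR_FLOOR = 1e-10
ALPHA_FLOOR = 1e-4


@dataclass
class GeneStats:
    """Per-gene intermediate quantities of the test (arrays over genes)."""

    mu_a: np.ndarray  # condition means
    mu_b: np.ndarray
    s2_a: np.ndarray  # condition sample variances (ddof=1; 0 when n=1)
    s2_b: np.ndarray
    s2_sum: np.ndarray  # s2_a + s2_b, or paired-difference variance
    mu: np.ndarray  # max(mu_a, mu_b)
    n: int  # max group size
    c: np.ndarray  # larger compensated group sum
    d: np.ndarray  # absolute-difference statistic (integer)
    sign: np.ndarray  # +1 if A > B, -1 if B > A, 0 on ties
    v: np.ndarray  # pooled dispersion (may be negative)
    v_hat: np.ndarray  # trend dispersion
    s2_hat: np.ndarray  # smoothed variance mu + v_hat mu^2
    mu0: np.ndarray  # pseudocount
    c_hat: np.ndarray  # c + n mu0
    mu_hat: np.ndarray  # mu + mu0
    v_bar: np.ndarray  # penalized dispersion (> 0)
    r_hat: np.ndarray  # 1 / v_bar
    eps: np.ndarray  # noise term added to c_hat
    m_hat: np.ndarray  # moderated NB mean


@dataclass
class ModelGlobals:
    """Experiment-wide moderation constants."""

    alpha: float  # general coefficient of variation
    theta: float  # background uncertainty across genes
    v0: float  # basic dispersion penalty
    beta: float  # fraction of genes with negative pooled dispersion
    r0: float  # common size used by fold-change moderation


# ----------------------------------------------------------------------
# Elementary operations


def group_sums_with_compensation(
    counts: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compensated group sums and the rounded absolute difference D.

    When group sizes differ, the smaller group's sum is augmented by
    (n_large - n_small) pseudo-replicates equal to its own mean before
    differencing, removing the larger group's head start on sum counts.
    """
    a = counts[:, idx_a]
    b = counts[:, idx_b]
    sum_a = a.sum(axis=1).astype(float)
    sum_b = b.sum(axis=1).astype(float)
    n_a, n_b = len(idx_a), len(idx_b)
    if n_a < n_b:
        sum_a += (n_b - n_a) * a.mean(axis=1)
    elif n_b < n_a:
        sum_b += (n_a - n_b) * b.mean(axis=1)
    d = round_half_away(np.abs(sum_a - sum_b)).astype(np.int64)
    return sum_a, sum_b, d


def pooled_dispersion(s2_sum: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Pooled dispersion v = ((s2_A + s2_B) - mu) / mu^2; 0 where mu = 0.

    Negative values signal underdispersion relative to Poisson and are
    retained — the penalty step later restores positivity.
    """
    mu = np.asarray(mu, dtype=float)
    v = np.zeros_like(mu)
    pos = mu > 0
    v[pos] = (np.asarray(s2_sum, dtype=float)[pos] - mu[pos]) / mu[pos] ** 2
    return v


def fit_mean_variance_trend(
    v: np.ndarray, mu: np.ndarray, span: float = 0.75, min_genes: int = 10
) -> np.ndarray:
    """Trend dispersion v_hat from a local regression of sqrt(v) on mu.

    Only genes with v > 0 inform the fit; the fitted curve is evaluated
    at every gene's mean (constant extrapolation beyond the fitted
    range), clipped at zero and squared. With fewer than ``min_genes``
    positive dispersions the fit degenerates to their mean (0 if none).
    """
    v = np.asarray(v, dtype=float)
    mu = np.asarray(mu, dtype=float)
    pos = v > 0
    if pos.sum() < min_genes:
        fill = float(v[pos].mean()) if pos.any() else 0.0
        return np.full(v.shape, fill)
    x = mu[pos]
    y = np.sqrt(v[pos])
    span_x = np.ptp(x)
    fitted = lowess(y, x, frac=span, delta=0.01 * span_x, return_sorted=True)
    f = np.interp(mu, fitted[:, 0], fitted[:, 1])
    return np.clip(f, 0.0, None) ** 2


def smoothed_variance(mu: np.ndarray, v_hat: np.ndarray) -> np.ndarray:
    """Expected variance under the trend: s2_hat = mu + v_hat * mu^2."""
    mu = np.asarray(mu, dtype=float)
    return mu + np.asarray(v_hat, dtype=float) * mu**2


def pseudocount_moderation(
    mu: np.ndarray, s2_hat: np.ndarray, c: np.ndarray, n: int, theta: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pseudocounts mu0 and the moderated c_hat, mu_hat.

    mu0 = sqrt((theta / mu) * s2_hat / (n - 1)) grows as expression
    falls, absorbing the larger relative uncertainty of low counts; it
    is added n times to the larger group sum and once to its mean.
    """
    if n < 2:
        raise ValueError("pseudocount moderation needs n >= 2 in the larger group")
    mu = np.asarray(mu, dtype=float)
    mu0 = np.zeros_like(mu)
    pos = mu > 0
    mu0[pos] = np.sqrt(theta / mu[pos] * np.asarray(s2_hat, dtype=float)[pos] / (n - 1))
    return mu0, np.asarray(c, dtype=float) + n * mu0, mu + mu0


def penalized_dispersion(
    v: np.ndarray, v_hat: np.ndarray, n: int, floor: float = V_BAR_FLOOR
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Basic penalty v0, underdispersed fraction beta, v_bar and r_hat.

    beta is the fraction of genes with v < 0; v0 is the sqrt(beta)
    quantile (linear interpolation) of the positive dispersions, so
    datasets with many underdispersed genes — evidence the trend fit
    underestimates — receive a harsher penalty. v_bar = v0 + v + v_hat/n
    floored at a tiny positive value keeps the NB size finite.
    """
    v = np.asarray(v, dtype=float)
    beta = float(np.mean(v < 0)) if v.size else 0.0
    positive = v[v > 0]
    v0 = float(np.quantile(positive, np.sqrt(beta))) if positive.size else 0.0
    v_bar = np.maximum(v0 + v + np.asarray(v_hat, dtype=float) / n, floor)
    return v0, beta, v_bar, 1.0 / v_bar


def estimate_alpha(
    counts: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    floor: float = ALPHA_FLOOR,
) -> float:
    """Experiment-wide CV alpha: mean per-gene residual SD on log2(c+1).

    Each gene's residual SD comes from the two-group-means linear model
    with pooled residual degrees of freedom n_A + n_B - 2 (the log-scale
    SD is the CV on the original scale). Floored to avoid a degenerate
    zero-mean null.
    """
    logc = np.log2(counts + 1.0)
    a = logc[:, idx_a]
    b = logc[:, idx_b]
    df = len(idx_a) + len(idx_b) - 2
    if df < 1:
        return floor
    ssr = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssr += ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return max(float(np.mean(np.sqrt(ssr / df))), floor)


def moderated_mean(
    c_hat: np.ndarray, s2_sum: np.ndarray, mu: np.ndarray, n: int, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Noise term eps = sqrt(n * max(s2_A + s2_B, mu)) and m_hat = alpha (c_hat + eps)."""
    eps = np.sqrt(n * np.maximum(np.asarray(s2_sum, dtype=float), np.asarray(mu, dtype=float)))
    return eps, alpha * (np.asarray(c_hat, dtype=float) + eps)


def pvalue(d, m_hat, r_hat):
    """Upper-tail NB p-value P(X >= D) with mean m_hat and size r_hat.

    The mean/size pair maps to scipy's success probability as
    prob = r / (r + m); P(X >= D) = sf(D - 1). D = 0 gives p = 1.
    """
    d = np.asarray(d)
    m_hat = np.asarray(m_hat, dtype=float)
    r_hat = np.asarray(r_hat, dtype=float)
    prob = r_hat / (r_hat + m_hat)
    return sps.nbinom.sf(d - 1, r_hat, prob)


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------
# Orchestration


def compute_gene_stats(
    counts: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    paired: bool = False,
    alpha: float | None = None,
    trend_span: float = 0.75,
) -> tuple[GeneStats, ModelGlobals]:
    """All per-gene statistics and moderation constants for a count table.

    ``counts`` is genes x samples, already normalized (and outlier
    replaced if requested); ``alpha`` overrides the estimated CV.
    """
    counts = np.asarray(counts, dtype=float)
    n_a, n_b = len(idx_a), len(idx_b)
    n = max(n_a, n_b)
    if n < 2:
        raise ValueError("at least 2 replicates in one condition are required")

    a = counts[:, idx_a]
    b = counts[:, idx_b]
    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)
    s2_a = a.var(axis=1, ddof=1) if n_a > 1 else np.zeros(counts.shape[0])
    s2_b = b.var(axis=1, ddof=1) if n_b > 1 else np.zeros(counts.shape[0])
    if paired:
        if n_a != n_b:
            raise ValueError("paired design requires equal group sizes")
        s2_sum = (a - b).var(axis=1, ddof=1)
    else:
        s2_sum = s2_a + s2_b

    sum_a, sum_b, d = group_sums_with_compensation(counts, idx_a, idx_b)
    # fold-change orientation: positive = higher in the second condition (B vs A)
    sign = np.sign(sum_b - sum_a).astype(np.int64)
    c = np.maximum(sum_a, sum_b)
    mu = np.maximum(mu_a, mu_b)

    v = pooled_dispersion(s2_sum, mu)
    v_hat = fit_mean_variance_trend(v, mu, span=trend_span)
    s2_hat = smoothed_variance(mu, v_hat)
    theta = float(np.sqrt(np.mean(s2_sum / 2.0))) if s2_sum.size else 0.0
    mu0, c_hat, mu_hat = pseudocount_moderation(mu, s2_hat, c, n, theta)
    v0, beta, v_bar, r_hat = penalized_dispersion(v, v_hat, n)
    alpha_val = estimate_alpha(counts, idx_a, idx_b) if alpha is None else max(float(alpha), ALPHA_FLOOR)
    eps, m_hat = moderated_mean(c_hat, s2_sum, mu, n, alpha_val)

    stats = GeneStats(
        mu_a=mu_a, mu_b=mu_b, s2_a=s2_a, s2_b=s2_b, s2_sum=s2_sum,
        mu=mu, n=n, c=c, d=d, sign=sign, v=v, v_hat=v_hat, s2_hat=s2_hat,
        mu0=mu0, c_hat=c_hat, mu_hat=mu_hat, v_bar=v_bar, r_hat=r_hat,
        eps=eps, m_hat=m_hat,
    )
    r0 = float(1.0 / np.mean(v_bar)) if v_bar.size else 0.0
    globs = ModelGlobals(alpha=alpha_val, theta=theta, v0=v0, beta=beta, r0=r0)
    return stats, globs


@dataclass
class TestResult:
    """Per-gene test output plus the three fold-change variants."""

    gene_ids: list[str]
    mean_a: np.ndarray
    mean_b: np.ndarray
    statistic: np.ndarray  # D
    pvalue: np.ndarray
    padj: np.ndarray
    log2fc_raw: np.ndarray
    log2fc_expr: np.ndarray
    log2fc_full: np.ndarray
    conditions: tuple[str, str] = ("A", "B")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "mean_A": self.mean_a,
                "mean_B": self.mean_b,
                "D": self.statistic,
                "pvalue": self.pvalue,
                "padj": self.padj,
                "log2FC_raw": self.log2fc_raw,
                "log2FC_expr": self.log2fc_expr,
                "log2FC_full": self.log2fc_full,
            }
        )


def run_test(cm: CountMatrix, **kwargs) -> TestResult:
    """Run the full pipeline (normalize, outliers, test, fold change) on a matrix.

    Thin wrapper over :class:`absdiff_de.estimators.AbsDiffDE`; keyword
    arguments are forwarded to the estimator (``normalization``,
    ``quantile``, ``outlier_filter``, ``mad_n0``, ``mad_sigma0``,
    ``alpha``, ``trend_span``).
    """
    from .estimators import AbsDiffDE

    est = AbsDiffDE(paired=cm.paired, **kwargs)
    est.fit(cm.counts.T, cm.labels())
    return TestResult(
        gene_ids=list(cm.gene_ids),
        mean_a=est.stats_.mu_a,
        mean_b=est.stats_.mu_b,
        statistic=est.statistic_,
        pvalue=est.pvalues_,
        padj=est.padj_,
        log2fc_raw=est.log2fc_raw_,
        log2fc_expr=est.log2fc_expr_,
        log2fc_full=est.log2fc_full_,
        conditions=cm.conditions,
    )
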