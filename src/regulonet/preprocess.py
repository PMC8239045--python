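"""Count normalization and per-gene standardization.

RNA-seq count matrices can be dominated by a handful of extremely highly
expressed transcripts, which artificially deflates the normalized values of
all other genes in those samples. ``dominance_diagnostic`` quantifies this
(top-k read fraction vs number of detected transcripts), and
``normalize_counts`` removes it with a trimmed-mean-of-M-values (TMM-like)
per-sample scaling followed by quantile normalization, so that every sample
shares the same value distribution. ``zscore_genes`` standardizes each gene
row for downstream correlation work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizationReport:
    scale_factors: pd.Series          # per-sample TMM scale factor (> 0)
    top_k_fraction: pd.Series         # per-sample fraction of reads in top k
    detected_transcripts: pd.Series   # per-sample genes with count > 0
    correlation: float                # Spearman(top-k fraction, detected)
    k: int
    flags: dict = field(default_factory=dict)


def _tmm_scale_factors(counts: np.ndarray, trim_fraction: float) -> np.ndarray:
    """Per-sample scale factors against the cohort's TMM reference sample.

    The reference is the sample whose 75th percentile of depth-scaled counts
    is closest to the cohort median of those percentiles; factors are
    2**mean(M) over genes kept after two-sided trimming of the most extreme
    M (log-ratio) and A (log-abundance) values.
    """
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("library size zero for at least one sample")
    scaled = counts / lib
    with np.errstate(invalid="ignore"):
        q75 = np.array([np.quantile(scaled[counts[:, j] > 0, j], 0.75)
                        for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(q75 - np.median(q75))))
    factors = np.ones(counts.shape[1])
    lo, hi = trim_fraction / 2, 1 - trim_fraction / 2
    for j in range(counts.shape[1]):
        both = (counts[:, j] > 0) & (counts[:, ref] > 0)
        if both.sum() < 2:
            continue
        m = np.log2(scaled[both, j] / scaled[both, ref])
        a = 0.5 * np.log2(scaled[both, j] * scaled[both, ref])
        m_lo, m_hi = np.quantile(m, [lo, hi])
        a_lo, a_hi = np.quantile(a, [lo, hi])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if keep.any():
            factors[j] = 2.0 ** np.mean(m[keep])
    return factors


def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Map every column onto the across-column mean of sorted values.

    Tied entries receive the mean of the reference values at their tied
    ranks, which keeps the procedure deterministic and order-preserving.
    """
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # tie-group boundaries in the sorted column
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [n]))
        mapped = np.empty(n)
        for s, e in zip(starts, stops):
            mapped[s:e] = ref[s:e].mean()
        out[order, j] = mapped
    return out


def dominance_diagnostic(expr: ExpressionMatrix, k: int = 10,
                         trim_fraction: float = 0.05) -> NormalizationReport:
    """Per-sample highly-expressed-gene dominance diagnostics.

    Reports, for each sample, the fraction of total counts carried by the k
    most expressed genes and the number of detected (count > 0) genes, plus
    the Spearman correlation between the two across samples. A strongly
    negative correlation is the signature of dominance-driven normalization
    artifacts.
    """
    if expr.state != "counts":
        raise ValueError("dominance_diagnostic requires state=counts")
    counts = expr.values
    totals = counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"all-zero sample(s): {[expr.sample_ids[j] for j in zero[:5]]}")
    kk = min(k, counts.shape[0])
    top = np.sort(counts, axis=0)[-kk:, :].sum(axis=0)
    top_frac = top / totals
    detected = (counts > 0).sum(axis=0)
    flags = {}
    if np.ptp(top_frac) == 0 or np.ptp(detected) == 0:
        corr = 0.0
        flags["zero_variance"] = True
    else:
        corr = float(stats.spearmanr(top_frac, detected).statistic)
    factors = _tmm_scale_factors(counts, trim_fraction)
    idx = expr.data.columns
    return NormalizationReport(
        scale_factors=pd.Series(factors, index=idx),
        top_k_fraction=pd.Series(top_frac, index=idx),
        detected_transcripts=pd.Series(detected, index=idx),
        correlation=corr, k=k, flags=flags)


def normalize_counts(expr: ExpressionMatrix,
                     trim_fraction: float = 0.05) -> ExpressionMatrix:
    """TMM-like scaling then quantile normalization of a count matrix.

    Genes with zero counts in every sample are dropped (their M values are
    undefined) with a logged list. The output state is ``normalized`` and all
    samples share an identical sorted value vector.
    """
    if expr.state != "counts":
        raise ValueError("normalize_counts requires state=counts")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    if not 0 <= trim_fraction <= 0.45:
        raise ValueError("trim_fraction must be in [0, 0.45]")
    data = expr.data
    all_zero = data.index[(data.to_numpy() == 0).all(axis=1)]
    if len(all_zero):
        logger.warning("dropping %d all-zero genes: %s", len(all_zero),
                       list(all_zero[:5]))
        data = data.drop(index=all_zero)
    counts = data.to_numpy(dtype=float)
    factors = _tmm_scale_factors(counts, trim_fraction)
    scaled = counts / counts.sum(axis=0) / factors
    out = _quantile_normalize(scaled)
    return ExpressionMatrix(pd.DataFrame(out, index=data.index,
                                         columns=data.columns),
                            state="normalized")


def zscore_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, variance 1 (population n).

    Constant rows are set to all-zero and listed under
    ``flags['constant_genes']``. Z-scoring an already z-scored matrix is a
    no-op.
    """
    if expr.state == "counts":
        raise ValueError("z-score normalized data, not raw counts")
    values = expr.values
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)   # population denominator
    const = sd[:, 0] <= 1e-12
    sd[const] = 1.0
    z = (values - mu) / sd
    z[const] = 0.0
    flagged = [expr.gene_ids[i] for i in np.flatnonzero(const)]
    if flagged:
        logger.warning("%d constant genes set to zero", len(flagged))
    return ExpressionMatrix(pd.DataFrame(z, index=expr.data.index,
                                         columns=expr.data.columns),
                            state="zscored",
                            flags={"constant_genes": flagged})


# ---------------------------------------------------------------------------
# sklearn-style estimators (X is samples x genes, the sklearn convention)
# ---------------------------------------------------------------------------

class CountNormalizer(BaseEstimator, TransformerMixin):
    """TMM-like scaling plus quantile mapping as an sklearn transformer.

    ``fit`` learns the reference quantile distribution from the training
    cohort; ``transform`` scales each sample by depth and maps its values
    onto that distribution by rank, so held-out samples are normalized
    consistently with the training cohort.
    """

    def __init__(self, trim_fraction: float = 0.05):
        self.trim_fraction = trim_fraction

    def fit(self, X, y=None):
        X = self._to_frame(X)
        expr = ExpressionMatrix(X.T, state="counts")
        normalized = normalize_counts(expr, self.trim_fraction)
        self.reference_distribution_ = np.sort(
            normalized.values[:, 0])  # identical across samples by construction
        self.gene_ids_ = list(normalized.data.index)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_distribution_")
        X = self._to_frame(X)
        cols = X[self.gene_ids_].to_numpy(dtype=float).T  # genes x samples
        lib = cols.sum(axis=0)
        if (lib == 0).any():
            raise ValueError("library size zero for at least one sample")
        scaled = cols / lib
        ref = self.reference_distribution_
        out = np.empty_like(scaled)
        for j in range(scaled.shape[1]):
            col = scaled[:, j]
            order = np.argsort(col, kind="mergesort")
            mapped = np.empty(col.shape[0])
            mapped[order] = ref
            out[:, j] = mapped
        return pd.DataFrame(out.T, index=X.index, columns=self.gene_ids_)

    @staticmethod
    def _to_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [str(c) for c in X.columns]
            X.index = [str(i) for i in X.index]
        return X


class GeneZScorer(BaseEstimator, TransformerMixin):
    """Per-gene standardization (population variance) as a transformer."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.constant_mask_ = scale <= 1e-12
        scale = np.where(self.constant_mask_, 1.0, scale)
        self.scale_ = scale
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        idx = cols = None
        if isinstance(X, pd.DataFrame):
            idx, cols = X.index, X.columns
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        Z[:, self.constant_mask_] = 0.0
        if idx is not None:
            return pd.DataFrame(Z, index=idx, columns=cols)
        return Z
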