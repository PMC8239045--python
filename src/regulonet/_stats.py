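"""Shared statistical primitives: vectorized rank-sum tests and exact
hypergeometric tail probabilities.

The rank-sum implementation mirrors the two-sided asymptotic Wilcoxon /
Mann-Whitney test (normal approximation with tie correction and continuity
correction) but operates on whole feature matrices and on many group-label
vectors at once, which is what the causal-flow permutation test needs.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def rank_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise average ranks and per-row tie-correction terms sum(t^3 - t)."""
    values = np.asarray(values, dtype=float)
    ranks = stats.rankdata(values, axis=1, method="average")
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(values[i], return_counts=True)
        t = counts[counts > 1].astype(float)
        tie_term[i] = np.sum(t ** 3 - t)
    return ranks, tie_term


def ranksum_z(ranks: np.ndarray, tie_term: np.ndarray,
              masks: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum z-scores for features x group-labelings.

    Parameters
    ----------
    ranks : (F, S) row-wise average ranks from :func:`rank_matrix`.
    tie_term : (F,) tie-correction terms.
    masks : (S,) boolean or (S, P) 0/1 matrix of group-1 indicators.

    Returns
    -------
    z : (F,) or (F, P) signed z-scores; positive means group 1 ranks higher.
    """
    masks = np.asarray(masks)
    squeeze = masks.ndim == 1
    if squeeze:
        masks = masks[:, None]
    masks = masks.astype(float)
    n = ranks.shape[1]
    n1 = masks.sum(axis=0)                       # (P,)
    n2 = n - n1
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("both groups must be non-empty")
    r1 = ranks @ masks                           # (F, P)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = (n1 * n2 / 12.0) * ((n + 1.0)
                              - tie_term[:, None] / (n * (n - 1.0)))
    var = np.maximum(var, 1e-300)
    diff = u1 - mu
    # continuity correction toward the mean, as in the standard asymptotic test
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return z[:, 0] if squeeze else z


def ranksum_p(z: np.ndarray) -> np.ndarray:
    """Two-sided p-values for rank-sum z-scores."""
    return 2.0 * stats.norm.sf(np.abs(z))


def hypergeometric_overlap(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for overlap k between a size-n draw and a
    size-K subset of an N-gene universe, evaluated in log space so that deep
    tails (p ~ 1e-85) keep full relative precision.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N or K > N:
        raise ValueError(
            f"require 0 <= k <= min(n, K) <= N, got k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    ks = np.arange(k, min(n, K) + 1)
    log_terms = stats.hypergeom.logpmf(ks, N, K, n)
    from scipy.special import logsumexp
    return float(np.exp(logsumexp(log_terms)))
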