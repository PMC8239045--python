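"""Per-sample discrete regulon activity and network-constrained gene activity.

Discrete activity uses the binomial tertile test: within each sample, all
genes are ranked and split into lower/middle/upper thirds. Under the null of
no co-regulation a regulon's N member genes scatter uniformly, so the count k
landing in one third is Binomial(N, 1/3); a regulon is called overexpressed
(+1) when the exact upper tail P(X >= k_upper) < alpha, underexpressed (-1)
symmetrically for the lower third, and 0 otherwise.

Network activity corrects a gene's z-scored expression toward the consensus
of the regulons that contain it: the sign-adjusted mean of the member-regulon
eigengenes, which acts as a mechanistically constrained denoiser.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix, Regulon
from .params import Parameters
from .regulons import eigengene_matrix

logger = logging.getLogger(__name__)


@lru_cache(maxsize=4096)
def minimal_significant_count(n: int, alpha: float = 0.05,
                              p: float = 1.0 / 3.0) -> int:
    """Smallest k with exact binomial upper tail P(X >= k | n, p) < alpha.

    Returns n + 1 when no count is significant.
    """
    tails = stats.binom.sf(np.arange(n + 1) - 1, n, p)  # P(X >= k), k=0..n
    hits = np.flatnonzero(tails < alpha)
    return int(hits[0]) if hits.size else n + 1


def tertile_membership(expr: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Boolean gene x sample masks for the lower and upper expression thirds.

    With G genes, each tested tail holds floor(G/3) genes (the middle keeps
    the remainder, which keeps the tail probability at or slightly below
    1/3). Rank ties are broken by stable row order, so results are
    deterministic.
    """
    values = expr.values
    G, S = values.shape
    third = G // 3
    lower = np.zeros((G, S), dtype=bool)
    upper = np.zeros((G, S), dtype=bool)
    for j in range(S):
        order = np.argsort(values[:, j], kind="stable")
        lower[order[:third], j] = True
        upper[order[G - third:], j] = True
        ties = G - len(np.unique(values[:, j]))
        if ties > 0.10 * G:
            logger.debug("sample %s has %d tied expression values",
                         expr.sample_ids[j], ties)
    return lower, upper


@dataclass
class ActivityMatrix:
    """Discrete {-1, 0, +1} regulon activity plus continuous eigengenes."""

    discrete: pd.DataFrame      # regulon x sample ints
    continuous: pd.DataFrame    # regulon x sample eigengene values

    @property
    def regulon_ids(self) -> list[str]:
        return list(self.discrete.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.discrete.columns)


def discrete_regulon_activity(
    expr: ExpressionMatrix,
    regulons: Sequence[Regulon],
    params: Optional[Parameters] = None,
    allow_missing: bool = False,
) -> ActivityMatrix:
    """Binomial tertile test for every regulon in every sample.

    Each regulon's genes must be present in the matrix; with
    ``allow_missing=True`` (for validation platforms that lack some genes)
    the test instead uses N = the present-gene count.
    """
    params = params or Parameters()
    if expr.state == "counts":
        raise ValueError("activity requires normalized or z-scored input")
    alpha = params.activity_alpha
    p0 = params.tertile_null_p
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}

    missing_report = {
        r.regulon_id: [g for g in r.gene_ids if g not in gene_index]
        for r in regulons}
    missing_report = {k: v for k, v in missing_report.items() if v}
    if missing_report and not allow_missing:
        raise ValueError(f"regulon genes absent from matrix: {missing_report}")

    lower, upper = tertile_membership(expr)
    S = expr.shape[1]
    discrete = np.zeros((len(regulons), S), dtype=int)
    for i, reg in enumerate(regulons):
        idx = [gene_index[g] for g in reg.gene_ids if g in gene_index]
        n = len(idx)
        if n == 0:
            continue
        k_up = upper[idx].sum(axis=0)
        k_lo = lower[idx].sum(axis=0)
        p_up = stats.binom.sf(k_up - 1, n, p0)
        p_lo = stats.binom.sf(k_lo - 1, n, p0)
        over = p_up < alpha
        under = p_lo < alpha
        if np.any(over & under):
            raise AssertionError(
                f"regulon {reg.regulon_id}: both tails significant in a "
                "sample; tertile partition violated")
        discrete[i] = over.astype(int) - under.astype(int)

    # continuous companion: eigengenes over the present member genes; rows
    # degenerate for eigengene computation (fewer than 2 present genes or 3
    # samples) are NaN so the discrete calls remain available regardless
    from .regulons import compute_eigengene

    ids = [r.regulon_id for r in regulons]
    continuous = pd.DataFrame(np.nan, index=ids, columns=expr.sample_ids)
    for reg in regulons:
        present = [g for g in reg.gene_ids if g in gene_index]
        if len(present) >= 2 and expr.shape[1] >= 3:
            try:
                continuous.loc[reg.regulon_id] = compute_eigengene(
                    expr.data.loc[present]).to_numpy()
            except ValueError:
                pass
    return ActivityMatrix(
        discrete=pd.DataFrame(discrete, index=ids, columns=expr.sample_ids),
        continuous=continuous,
    )


@dataclass
class NetworkActivityMatrix:
    """Network-constrained gene activity with per-gene regulon membership."""

    data: pd.DataFrame            # gene x sample
    membership_counts: pd.Series  # regulons containing each gene
    fallback_genes: tuple[str, ...] = ()


def network_activity(
    expr: ExpressionMatrix,
    regulons: Sequence[Regulon],
    min_memberships: int = 1,
) -> NetworkActivityMatrix:
    """Sign-adjusted mean of member-regulon eigengenes per gene.

    For gene g in sample s the activity is the mean over regulons R
    containing g of sign(corr(g, eigengene_R)) * eigengene_R(s). Genes in no
    regulon fall back to their z-score and are flagged. With
    ``min_memberships >= 2`` the output is restricted to genes appearing in
    at least that many regulons.
    """
    if expr.state != "zscored":
        raise ValueError("network_activity requires z-scored input")
    eig = eigengene_matrix(regulons, expr)
    data = expr.data
    membership: dict[str, list[str]] = {}
    for r in regulons:
        for g in r.gene_ids:
            if g in data.index:
                membership.setdefault(g, []).append(r.regulon_id)

    counts = pd.Series({g: len(membership.get(g, [])) for g in data.index})
    rows = {}
    fallback = []
    for g in data.index:
        regs = membership.get(g, [])
        if len(regs) < min_memberships:
            if min_memberships > 1:
                continue
        if not regs:
            rows[g] = data.loc[g].to_numpy()
            fallback.append(g)
            continue
        grow = data.loc[g].to_numpy()
        acc = np.zeros(data.shape[1])
        for rid in regs:
            e = eig.loc[rid].to_numpy()
            sign = np.sign(np.corrcoef(grow, e)[0, 1]) or 1.0
            acc += sign * e
        rows[g] = acc / len(regs)
    out = pd.DataFrame(rows, index=data.columns).T
    return NetworkActivityMatrix(
        data=out,
        membership_counts=counts.loc[out.index],
        fallback_genes=tuple(fallback))


class RegulonActivity(BaseEstimator, TransformerMixin):
    """Transformer: samples x genes expression -> samples x regulons activity.

    ``kind`` selects discrete {-1,0,1} calls (the tertile test), continuous
    eigengenes, or network-constrained gene activity (samples x genes).
    """

    def __init__(self, regulons: Optional[Sequence[Regulon]] = None,
                 kind: str = "discrete",
                 params: Optional[Parameters] = None,
                 allow_missing: bool = False,
                 min_memberships: int = 1):
        self.regulons = regulons
        self.kind = kind
        self.params = params
        self.allow_missing = allow_missing
        self.min_memberships = min_memberships

    def fit(self, X, y=None):
        if self.regulons is None:
            raise ValueError("RegulonActivity requires regulons")
        if self.kind not in ("discrete", "continuous", "network"):
            raise ValueError(f"unknown kind {self.kind!r}")
        self.n_features_in_ = X.shape[1]
        self.fitted_ = True
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "fitted_")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame")
        expr = ExpressionMatrix(X.T, state="normalized")
        if self.kind == "network":
            from .preprocess import zscore_genes
            expr = zscore_genes(expr)
            return network_activity(expr, self.regulons,
                                    self.min_memberships).data.T
        act = discrete_regulon_activity(expr, self.regulons, self.params,
                                        self.allow_missing)
        mat = act.discrete if self.kind == "discrete" else act.continuous
        return mat.T
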