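"""Coexpression clustering and regulon inference.

A regulon is a coexpressed gene cluster restricted to the genes that share a
binding site for one regulator in the prior, with a signed regulatory edge.
Three gates define it: binding-site enrichment in the cluster (hypergeometric
p < 0.05 against the whole expression universe), at least 5 member genes, and
|Pearson correlation| >= 0.2 between the regulator's expression and the
regulon eigengene (the first principal component of the member genes). The
sign of that correlation is the edge sign: activator (+1) or repressor (-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from ._stats import hypergeometric_overlap
from .io import ExpressionMatrix, GeneSetLibrary, Regulon
from .params import Parameters
from .preprocess import zscore_genes

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionCluster:
    cluster_id: str
    gene_ids: tuple[str, ...]
    eigengene: pd.Series

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)


def compute_eigengene(data: pd.DataFrame) -> pd.Series:
    """First principal component of a gene x sample submatrix.

    Rows are standardized (population variance) before the SVD; the returned
    per-sample score vector is scaled to unit variance and sign-oriented to
    correlate positively with the mean raw expression of the gene set. When
    that mean profile is exactly flat (e.g. a {g, -g} pair), orientation
    falls back to positive correlation with the first gene row.
    """
    if data.shape[0] < 2:
        raise ValueError("eigengene needs at least 2 genes")
    if data.shape[1] < 3:
        raise ValueError("eigengene needs at least 3 samples")
    X = data.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    nonconst = sd[:, 0] > 1e-12
    if not nonconst.any():
        raise ValueError("zero-variance submatrix")
    Z = np.zeros_like(X)
    Z[nonconst] = (X[nonconst] - mu[nonconst]) / sd[nonconst]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    scores = vt[0]
    sd_scores = scores.std()
    if sd_scores <= 1e-15:
        raise ValueError("degenerate eigengene (zero variance)")
    scores = (scores - scores.mean()) / sd_scores
    mean_profile = X.mean(axis=0)
    if mean_profile.std() > 1e-12:
        orient = np.corrcoef(scores, mean_profile)[0, 1]
    else:
        orient = np.corrcoef(scores, X[0])[0, 1] if X[0].std() > 1e-12 else 1.0
    if orient < 0:
        scores = -scores
    return pd.Series(scores, index=data.columns)


def _mean_pairwise_corr(corr: np.ndarray, idx: np.ndarray) -> float:
    sub = corr[np.ix_(idx, idx)]
    m = len(idx)
    return float((sub.sum() - m) / (m * (m - 1)))


def cluster_coexpression(
    expr: ExpressionMatrix,
    params: Optional[Parameters] = None,
    seed: int = 0,
) -> tuple[list[CoexpressionCluster], list[str]]:
    """Discover disjoint coexpressed gene clusters of size >= 6.

    Agglomerative clustering (average linkage) on correlation distance
    (1 - Pearson), cut at ``params.cluster_cut_height``; genes left out are
    re-assigned once to the cluster whose eigengene they correlate with best
    (if r >= 1 - cut). Every reported cluster must beat size-matched random
    gene sets on mean pairwise correlation (permutation p < 0.05); remaining
    genes are returned as unclustered.
    """
    params = params or Parameters()
    if expr.state != "zscored":
        raise ValueError("cluster_coexpression requires z-scored input")
    if expr.shape[1] < 10:
        raise ValueError("need at least 10 samples for stable correlations")
    if expr.shape[0] < params.min_cluster_genes:
        # too few genes to form any qualifying cluster: all unclustered
        return [], sorted(expr.gene_ids)
    data = expr.data
    variable = data.std(axis=1) > 1e-12
    data = data.loc[variable]
    genes = np.array(data.index)
    X = data.to_numpy()
    corr = np.corrcoef(X)
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=params.cluster_cut_height,
                                criterion="distance")

    members: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        members.setdefault(lab, []).append(i)
    big = {lab: idx for lab, idx in members.items()
           if len(idx) >= params.min_cluster_genes}
    unclustered = [i for lab, idx in members.items()
                   if lab not in big for i in idx]

    # one re-assignment pass of leftover genes onto cluster eigengenes
    if big and unclustered:
        eigs = {lab: compute_eigengene(data.iloc[idx]).to_numpy()
                for lab, idx in big.items()}
        threshold = 1.0 - params.cluster_cut_height
        still = []
        for i in unclustered:
            row = X[i]
            best_lab, best_r = None, -np.inf
            for lab, eig in eigs.items():
                r = np.corrcoef(row, eig)[0, 1]
                if r > best_r:
                    best_lab, best_r = lab, r
            if best_r >= threshold:
                big[best_lab].append(i)
            else:
                still.append(i)
        unclustered = still

    # permutation filter: clusters must be tighter than random gene sets
    rng = np.random.default_rng(seed)
    n_perm = params.cluster_filter_permutations
    kept: list[list[int]] = []
    for lab in sorted(big, key=lambda l: (-len(big[l]), genes[min(big[l])])):
        idx = np.array(sorted(big[lab]))
        obs = _mean_pairwise_corr(corr, idx)
        null = np.array([
            _mean_pairwise_corr(
                corr, rng.choice(len(genes), size=len(idx), replace=False))
            for _ in range(n_perm)])
        p = (1 + np.sum(null >= obs)) / (n_perm + 1)
        if p < 0.05:
            kept.append(list(idx))
        else:
            unclustered.extend(idx)

    clusters = []
    order = sorted(range(len(kept)),
                   key=lambda i: (-len(kept[i]), genes[min(kept[i])]))
    for rank, i in enumerate(order):
        idx = kept[i]
        gene_ids = tuple(sorted(genes[idx]))
        clusters.append(CoexpressionCluster(
            cluster_id=f"C-{rank:04d}",
            gene_ids=gene_ids,
            eigengene=compute_eigengene(data.loc[list(gene_ids)])))
    unassigned = sorted(genes[sorted(set(unclustered))])
    return clusters, list(unassigned)


def infer_regulons(
    clusters: Sequence[CoexpressionCluster],
    prior: GeneSetLibrary,
    expr: ExpressionMatrix,
    params: Optional[Parameters] = None,
) -> list[Regulon]:
    """Convert coexpressed clusters into signed regulons via the prior.

    For every (cluster, regulator) pair whose prior targets are enriched in
    the cluster (hypergeometric p < ``max_enrichment_p`` against the full
    expression universe), the candidate regulon is cluster-intersect-targets;
    it is emitted when it has >= ``min_regulon_genes`` members and the
    regulator's expression correlates with the candidate eigengene at
    |r| >= ``min_abs_regulator_corr``. One cluster may yield several regulons.
    """
    params = params or Parameters()
    if len(prior) == 0:
        raise ValueError("empty prior")
    universe = set(expr.gene_ids)
    N = len(universe)
    data = expr.data
    skipped = [r for r in prior.regulators() if r not in universe]
    if skipped:
        logger.warning("%d regulators absent from expression, skipped: %s",
                       len(skipped), skipped[:5])

    candidates = []  # (cluster, regulator, candidate_genes, p)
    pvals = []
    for cluster in clusters:
        cluster_set = set(cluster.gene_ids)
        n = len(cluster_set)
        for regulator in prior.regulators():
            if regulator not in universe:
                continue
            targets = set(prior[regulator]) & universe
            if not targets:
                continue
            overlap = cluster_set & targets
            if len(overlap) < params.min_regulon_genes:
                continue
            p = hypergeometric_overlap(len(overlap), n, len(targets), N)
            candidates.append((cluster, regulator, tuple(sorted(overlap)), p))
            pvals.append(p)

    if params.bh_correction and pvals:
        from statsmodels.stats.multitest import multipletests
        adjusted = multipletests(pvals, method="fdr_bh")[1]
    else:
        adjusted = pvals

    regulons: list[Regulon] = []
    for (cluster, regulator, genes, p_raw), p in zip(candidates, adjusted):
        if p >= params.max_enrichment_p:
            continue
        eig = compute_eigengene(data.loc[list(genes)])
        reg_expr = data.loc[regulator].to_numpy()
        if reg_expr.std() <= 1e-12:
            continue
        r = float(np.corrcoef(reg_expr, eig.to_numpy())[0, 1])
        if abs(r) < params.min_abs_regulator_corr:
            continue
        regulons.append(Regulon(
            regulon_id=f"{cluster.cluster_id}:{regulator}",
            regulator_id=regulator,
            edge_sign=1 if r > 0 else -1,
            gene_ids=genes,
            regulator_corr=r,
            enrichment_p=float(p_raw),
            eigengene=eig,
        ))
    return regulons


def eigengene_matrix(regulons: Sequence[Regulon],
                     expr: Optional[ExpressionMatrix] = None) -> pd.DataFrame:
    """Regulon x sample matrix of eigengenes (recomputed on ``expr`` if given)."""
    rows = {}
    for r in regulons:
        if expr is not None:
            rows[r.regulon_id] = compute_eigengene(
                expr.data.loc[list(r.gene_ids)])
        else:
            if r.eigengene is None:
                raise ValueError(f"regulon {r.regulon_id} has no eigengene; "
                                 "pass an expression matrix")
            rows[r.regulon_id] = r.eigengene
    return pd.DataFrame(rows).T


class RegulonDiscovery(BaseEstimator):
    """Sklearn-style estimator wrapping clustering plus regulon inference.

    ``fit`` takes a samples x genes DataFrame (z-scored or normalized; counts
    must be normalized first) and a regulator -> targets prior, and exposes
    ``clusters_``, ``unclustered_``, ``regulons_`` and ``eigengenes_``.
    """

    def __init__(self, prior: Optional[GeneSetLibrary] = None,
                 params: Optional[Parameters] = None, seed: int = 0):
        self.prior = prior
        self.params = params
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        if self.prior is None:
            raise ValueError("RegulonDiscovery requires a prior")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame with "
                            "gene names as columns")
        params = self.params or Parameters()
        expr = ExpressionMatrix(X.T, state="normalized")
        expr = zscore_genes(expr)
        self.clusters_, self.unclustered_ = cluster_coexpression(
            expr, params, seed=self.seed)
        self.regulons_ = infer_regulons(self.clusters_, self.prior, expr,
                                        params)
        self.eigengenes_ = eigengene_matrix(self.regulons_)
        self.n_features_in_ = X.shape[1]
        return self
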