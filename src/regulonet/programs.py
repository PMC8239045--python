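"""Genetic programs, transcriptional states, differential regulon expression,
and program coherence testing.

Programs are clusters of regulons with similar continuous activity across
samples; transcriptional states are clusters of samples with similar discrete
activity across the whole network. Both use deterministic agglomerative
clustering so that rerunning on the same cohort reproduces the same partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .activity import ActivityMatrix
from .io import ExpressionMatrix, Program, StateAssignment, UNASSIGNED
from .params import Parameters


def discover_programs(activity: ActivityMatrix,
                      params: Optional[Parameters] = None) -> list[Program]:
    """Cluster regulons into programs on continuous-activity correlation.

    Average-linkage agglomerative clustering on 1 - Pearson, cut at
    ``params.program_cut_height``; any multi-member program whose mean
    pairwise activity correlation is not positive is split into singletons,
    so every emitted program co-varies positively. Singletons are allowed.
    """
    params = params or Parameters()
    cont = activity.continuous
    if cont.shape[0] < 2:
        raise ValueError("need at least 2 regulons")
    X = cont.to_numpy()
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=params.program_cut_height,
                                criterion="distance")
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)

    final: list[list[int]] = []
    for lab in sorted(groups):
        idx = groups[lab]
        if len(idx) > 1:
            sub = corr[np.ix_(idx, idx)]
            mean_pair = (sub.sum() - len(idx)) / (len(idx) * (len(idx) - 1))
            if mean_pair <= 0:
                final.extend([[i] for i in idx])
                continue
        final.append(idx)

    ids = np.array(cont.index)
    final.sort(key=lambda idx: (-len(idx), ids[min(idx)]))
    return [Program(program_id=f"Pr-{k}",
                    regulon_ids=tuple(sorted(ids[i] for i in idx)))
            for k, idx in enumerate(final)]


def _centroid(block: np.ndarray) -> np.ndarray:
    """Elementwise majority sign of a regulon x sample activity block."""
    pos = (block == 1).sum(axis=1)
    neg = (block == -1).sum(axis=1)
    zero = (block == 0).sum(axis=1)
    out = np.zeros(block.shape[0], dtype=int)
    out[(pos > neg) & (pos > zero)] = 1
    out[(neg > pos) & (neg > zero)] = -1
    return out


def discover_states(activity: ActivityMatrix,
                    params: Optional[Parameters] = None) -> StateAssignment:
    """Cluster samples into transcriptional states on discrete activity.

    Average-linkage clustering on normalized Hamming distance, cut at
    1 - ``state_similarity_threshold``; clusters smaller than
    ``min_state_size`` are dissolved. Every sample is then assigned to the
    surviving centroid (elementwise majority activity) it is most similar
    to, or UNASSIGNED when no similarity reaches the threshold.
    """
    params = params or Parameters()
    disc = activity.discrete
    if disc.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = disc.to_numpy().T.astype(float)          # samples x regulons
    dist = pdist(X, metric="hamming")
    link = hierarchy.linkage(dist, method="average")
    labels = hierarchy.fcluster(
        link, t=1.0 - params.state_similarity_threshold, criterion="distance")
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    surviving = [idx for idx in groups.values()
                 if len(idx) >= params.min_state_size]
    samples = np.array(disc.columns)
    surviving.sort(key=lambda idx: (-len(idx), samples[min(idx)]))

    Xi = disc.to_numpy()                         # regulons x samples
    centroids = {}
    for k, idx in enumerate(surviving):
        centroids[f"TS-{k}"] = _centroid(Xi[:, idx])
    centroid_df = pd.DataFrame(centroids, index=disc.index, dtype=int)

    assignments: dict[str, str] = {}
    if centroid_df.shape[1]:
        C = centroid_df.to_numpy()               # regulons x states
        sim = 1.0 - (Xi[:, :, None] != C[:, None, :]).mean(axis=0)
        best = sim.argmax(axis=1)
        for j, s in enumerate(samples):
            if sim[j, best[j]] >= params.state_similarity_threshold:
                assignments[s] = f"TS-{best[j]}"
            else:
                assignments[s] = UNASSIGNED
    else:
        assignments = {s: UNASSIGNED for s in samples}
    return StateAssignment(assignments=assignments, centroids=centroid_df)


@dataclass
class DifferentialResult:
    regulon_id: str
    mean_a: float
    mean_b: float
    statistic: float
    p_value: float
    direction: int
    significant: bool


def differential_regulon_expression(
    eigengenes: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> list[DifferentialResult]:
    """Two-sided Wilcoxon rank-sum on eigengenes between two sample groups."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    A = eigengenes[group_a].to_numpy()
    B = eigengenes[group_b].to_numpy()
    stat, p = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided",
                                 method="asymptotic")
    if bh_correction:
        from statsmodels.stats.multitest import multipletests
        p_adj = multipletests(p, method="fdr_bh")[1]
    else:
        p_adj = p
    out = []
    for i, rid in enumerate(eigengenes.index):
        ma, mb = float(A[i].mean()), float(B[i].mean())
        out.append(DifferentialResult(
            regulon_id=rid, mean_a=ma, mean_b=mb,
            statistic=float(stat[i]), p_value=float(p_adj[i]),
            direction=int(np.sign(ma - mb)) or 0,
            significant=bool(p_adj[i] < alpha)))
    return out


def program_coherence_test(
    expr_test: ExpressionMatrix,
    gene_ids: Sequence[str],
    n_perm: int = 500,
    seed: int = 0,
) -> float:
    """Permutation test of a gene set's expression coherence in a new cohort.

    The statistic is the mean over samples of the across-gene variance; a
    coherent program moves together, so its within-sample variance is lower
    than that of random gene selections of the same size. Returns the
    fraction of ``n_perm`` size-matched random gene sets whose statistic is
    <= the observed one (small p means coherent).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    present = [g for g in gene_ids if g in expr_test.data.index]
    if len(present) < 2:
        raise ValueError("fewer than 2 program genes present in expression")
    data = expr_test.values
    gene_pos = {g: i for i, g in enumerate(expr_test.gene_ids)}
    idx = np.array([gene_pos[g] for g in present])
    obs = data[idx].var(axis=0, ddof=1).mean()
    rng = np.random.default_rng(seed)
    m = len(idx)
    null = np.empty(n_perm)
    for b in range(n_perm):
        sel = rng.choice(data.shape[0], size=m, replace=False)
        null[b] = data[sel].var(axis=0, ddof=1).mean()
    return float(np.mean(null <= obs))
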