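"""Regulon-set benchmarking and gene-signature overlap statistics.

Any regulon set (this package's or an external tool's) is scored on three
metrics: (1) coherence — each regulon's within-sample gene-expression
variance against size-matched random gene sets; (2) mechanistic support —
hypergeometric enrichment of each regulon's genes in its regulator's prior
binding-site targets; (3) topology preservation — Spearman correlation
between pairwise sample distances in gene-expression space and in continuous
regulon-activity space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from ._stats import hypergeometric_overlap
from .io import ExpressionMatrix, GeneSetLibrary, Regulon
from .programs import program_coherence_test
from .regulons import eigengene_matrix

__all__ = ["BenchmarkReport", "benchmark_regulons", "hypergeometric_overlap"]


@dataclass
class BenchmarkReport:
    coherence_p: pd.Series          # per-regulon permutation p
    enrichment_p: pd.Series         # per-regulon hypergeometric p
    topology_spearman: float
    alpha: float = 0.05

    @property
    def coherent_fraction(self) -> float:
        return float((self.coherence_p < self.alpha).mean())

    @property
    def enriched_fraction(self) -> float:
        return float((self.enrichment_p < self.alpha).mean())


def benchmark_regulons(
    regulons: Sequence[Regulon],
    expr: ExpressionMatrix,
    prior: GeneSetLibrary,
    n_perm: int = 500,
    seed: int = 0,
    activity: Optional[pd.DataFrame] = None,
) -> BenchmarkReport:
    """Score a regulon set with the three benchmark metrics.

    ``activity`` overrides the regulon-activity space used for the topology
    metric (continuous regulon x sample values); by default the eigengene
    matrix is recomputed from ``expr``.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for pairwise distances")
    universe = set(expr.gene_ids)
    N = len(universe)

    coh = {}
    enr = {}
    for i, r in enumerate(regulons):
        coh[r.regulon_id] = program_coherence_test(
            expr, r.gene_ids, n_perm=n_perm, seed=seed + i)
        targets = (set(prior[r.regulator_id]) & universe
                   if r.regulator_id in prior else set())
        present = [g for g in r.gene_ids if g in universe]
        k = len(set(present) & targets)
        if targets and present:
            enr[r.regulon_id] = hypergeometric_overlap(
                k, len(present), len(targets), N)
        else:
            enr[r.regulon_id] = 1.0

    if activity is None:
        activity = eigengene_matrix(regulons, expr)
    d_expr = pdist(expr.values.T, metric="euclidean")
    d_act = pdist(activity.to_numpy().T, metric="euclidean")
    rho = float(stats.spearmanr(d_expr, d_act).statistic)

    return BenchmarkReport(
        coherence_p=pd.Series(coh),
        enrichment_p=pd.Series(enr),
        topology_spearman=rho)
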