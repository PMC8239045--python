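"""Shared fixtures: one default synthetic cohort and its inferred network.

The cohort is generated once per session at the generator's default study
conditions (300 samples, 10 regulators x 15 signed targets, 500 noise genes,
10 causal + 90 null mutations) and pushed through clustering, regulon
inference and activity scoring, so the expensive stages run once.
"""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from regulonet import (ExpressionMatrix, Regulon, cluster_coexpression,
                       discrete_regulon_activity, infer_regulons,
                       simulate_dataset, zscore_genes)


@pytest.fixture(scope="session")
def cohort():
    expr, prior, mut, surv, truth = simulate_dataset(seed=0)
    return SimpleNamespace(expr=expr, prior=prior, mutations=mut,
                           survival=surv, truth=truth)


@pytest.fixture(scope="session")
def pipeline(cohort):
    z = zscore_genes(cohort.expr)
    clusters, unclustered = cluster_coexpression(z, seed=0)
    regulons = infer_regulons(clusters, cohort.prior, z)
    activity = discrete_regulon_activity(cohort.expr, regulons)
    return SimpleNamespace(z=z, clusters=clusters, unclustered=unclustered,
                           regulons=regulons, activity=activity, **vars(cohort))


@pytest.fixture(scope="session")
def planted_regulons(cohort):
    """The ground-truth regulons as Regulon objects."""
    out = []
    for pid, info in cohort.truth.regulons.items():
        out.append(Regulon(regulon_id=pid, regulator_id=info["regulator"],
                           edge_sign=info["sign"],
                           gene_ids=tuple(info["genes"]),
                           regulator_corr=float(info["sign"])))
    return out


@pytest.fixture()
def tiny_expr():
    """A deterministic 6-gene x 12-sample normalized matrix."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(rng.normal(5, 2, size=(6, 12)),
                        index=[f"g{i}" for i in range(6)],
                        columns=[f"s{j}" for j in range(12)])
    return ExpressionMatrix(data, state="normalized")
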