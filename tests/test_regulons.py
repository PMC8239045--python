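import numpy as np
import pandas as pd
import pytest

from regulonet import (ExpressionMatrix, GeneSetLibrary, Parameters,
                       RegulonDiscovery, cluster_coexpression,
                       compute_eigengene, infer_regulons, zscore_genes)


def _zscored(df):
    return zscore_genes(ExpressionMatrix(df, "normalized"))


class TestEigengene:
    def test_two_identical_rows_proportional_to_row(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(20)
        df = pd.DataFrame([row, row], index=["a", "b"],
                          columns=[f"s{j}" for j in range(20)])
        eig = compute_eigengene(df)
        assert abs(np.corrcoef(eig, row)[0, 1] - 1.0) < 1e-9

    def test_unit_variance_contract(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((5, 30)))
        df.columns = [f"s{j}" for j in range(30)]
        assert abs(compute_eigengene(df).std(ddof=0) - 1.0) < 1e-9

    def test_orientation_follows_dominant_gene(self):
        # set {g, -0.5 g}: the mean profile follows g, so the eigengene must
        # correlate positively with g
        rng = np.random.default_rng(2)
        g = rng.standard_normal(25)
        df = pd.DataFrame([g, -0.5 * g], index=["g", "anti"],
                          columns=[f"s{j}" for j in range(25)])
        eig = compute_eigengene(df)
        assert np.corrcoef(eig, g)[0, 1] > 0.99

    def test_degenerate_inputs_rejected(self):
        const = pd.DataFrame(np.ones((3, 5)), columns=list("abcde"))
        with pytest.raises(ValueError, match="zero-variance"):
            compute_eigengene(const)
        with pytest.raises(ValueError, match="2 genes"):
            compute_eigengene(const.iloc[:1])
        with pytest.raises(ValueError, match="3 samples"):
            compute_eigengene(const.iloc[:, :2])


def _planted_blocks(seed=0, block=20, noise=50, n_samples=60, noise_sd=0.3):
    rng = np.random.default_rng(seed)
    l1, l2 = rng.standard_normal(n_samples), rng.standard_normal(n_samples)
    rows, names = [], []
    for i in range(block):
        rows.append(l1 + rng.normal(0, noise_sd, n_samples))
        names.append(f"b1_{i:02d}")
    for i in range(block):
        rows.append(l2 + rng.normal(0, noise_sd, n_samples))
        names.append(f"b2_{i:02d}")
    for i in range(noise):
        rows.append(rng.standard_normal(n_samples))
        names.append(f"nz_{i:02d}")
    df = pd.DataFrame(rows, index=names,
                      columns=[f"s{j}" for j in range(n_samples)])
    return _zscored(df)


class TestClusterCoexpression:
    def test_planted_blocks_recovered_exactly(self):
        z = _planted_blocks(seed=0)
        clusters, unclustered = cluster_coexpression(z, seed=0)
        assert len(clusters) == 2
        found = {frozenset(c.gene_ids) for c in clusters}
        want = {frozenset(f"b1_{i:02d}" for i in range(20)),
                frozenset(f"b2_{i:02d}" for i in range(20))}
        assert found == want  # Jaccard 1.0 for both blocks
        assert len(unclustered) == 50

    def test_five_correlated_genes_yield_no_cluster(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(30)
        df = pd.DataFrame([base + rng.normal(0, 0.01, 30) for _ in range(5)],
                          index=[f"g{i}" for i in range(5)],
                          columns=[f"s{j}" for j in range(30)])
        clusters, unclustered = cluster_coexpression(_zscored(df))
        assert clusters == [] and len(unclustered) == 5

    def test_gene_order_permutation_invariant(self):
        z = _planted_blocks(seed=3)
        perm = list(np.random.default_rng(9).permutation(z.gene_ids))
        z_perm = ExpressionMatrix(z.data.loc[perm], "zscored")
        c1, _ = cluster_coexpression(z, seed=0)
        c2, _ = cluster_coexpression(z_perm, seed=0)
        assert ({frozenset(c.gene_ids) for c in c1}
                == {frozenset(c.gene_ids) for c in c2})

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((20, 5)),
                          columns=[f"s{j}" for j in range(5)])
        with pytest.raises(ValueError, match="10 samples"):
            cluster_coexpression(_zscored(df))


def _planted_tf(seed=0, n_targets=10, corr_noise=0.3, regulator_noise=None):
    """One TF driving n targets; regulator row optionally replaced by noise."""
    rng = np.random.default_rng(seed)
    n = 80
    tf = rng.standard_normal(n)
    rows = {"TF1": tf if regulator_noise is None
            else rng.standard_normal(n)}
    for i in range(n_targets):
        rows[f"t{i:02d}"] = tf + rng.normal(0, corr_noise, n)
    for i in range(40):
        rows[f"nz{i:02d}"] = rng.standard_normal(n)
    df = pd.DataFrame(rows, index=[f"s{j}" for j in range(n)]).T
    return _zscored(df)


class TestInferRegulons:
    def test_planted_tf_yields_one_activating_regulon(self):
        z = _planted_tf(seed=0)
        prior = GeneSetLibrary({"TF1": {f"t{i:02d}" for i in range(10)}})
        clusters, _ = cluster_coexpression(z, seed=0)
        regulons = infer_regulons(clusters, prior, z)
        assert len(regulons) == 1
        r = regulons[0]
        assert r.edge_sign == 1 and len(r.gene_ids) == 10
        assert r.regulator_corr > 0.9

    def test_uncorrelated_regulator_rejected(self):
        z = _planted_tf(seed=1, regulator_noise=True)
        prior = GeneSetLibrary({"TF1": {f"t{i:02d}" for i in range(10)}})
        clusters, _ = cluster_coexpression(z, seed=0)
        assert infer_regulons(clusters, prior, z) == []

    def test_repressed_targets_get_negative_edge(self):
        rng = np.random.default_rng(5)
        n = 80
        tf = rng.standard_normal(n)
        rows = {"TF1": tf}
        for i in range(8):
            rows[f"t{i}"] = -tf + rng.normal(0, 0.3, n)
        for i in range(30):
            rows[f"nz{i}"] = rng.standard_normal(n)
        z = _zscored(pd.DataFrame(rows, index=[f"s{j}" for j in range(n)]).T)
        prior = GeneSetLibrary({"TF1": {f"t{i}" for i in range(8)}})
        clusters, _ = cluster_coexpression(z, seed=0)
        regulons = infer_regulons(clusters, prior, z)
        assert len(regulons) == 1 and regulons[0].edge_sign == -1

    def test_small_prior_overlap_rejected(self):
        z = _planted_tf(seed=2, n_targets=8)
        # only 4 of the 8 cluster genes are prior targets: below the size gate
        prior = GeneSetLibrary({"TF1": {f"t{i:02d}" for i in range(4)}})
        clusters, _ = cluster_coexpression(z, seed=0)
        assert infer_regulons(clusters, prior, z) == []

    def test_empty_prior_rejected(self, pipeline):
        with pytest.raises(ValueError, match="empty prior"):
            infer_regulons(pipeline.clusters, GeneSetLibrary({}), pipeline.z)

    def test_all_three_gates_hold_for_every_regulon(self, pipeline):
        params = Parameters()
        universe = set(pipeline.z.gene_ids)
        for r in pipeline.regulons:
            assert len(r.gene_ids) >= params.min_regulon_genes
            assert abs(r.regulator_corr) >= params.min_abs_regulator_corr
            assert r.enrichment_p < params.max_enrichment_p
            assert np.sign(r.regulator_corr) == r.edge_sign
            assert set(r.gene_ids) <= set(pipeline.prior[r.regulator_id])
            assert set(r.gene_ids) <= universe


class TestRegulonDiscoveryEstimator:
    def test_fit_exposes_network_attributes(self, cohort):
        est = RegulonDiscovery(prior=cohort.prior, seed=0)
        est.fit(cohort.expr.data.T)
        assert len(est.regulons_) > 0
        assert est.eigengenes_.shape[1] == cohort.expr.shape[1]
        assert est.n_features_in_ == cohort.expr.shape[0]

    def test_get_set_params_roundtrip(self, cohort):
        est = RegulonDiscovery(prior=cohort.prior, seed=5)
        assert est.get_params()["seed"] == 5
        est.set_params(seed=7)
        assert est.seed == 7
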