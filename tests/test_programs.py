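import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from regulonet import (ActivityMatrix, ExpressionMatrix, Parameters,
                       UNASSIGNED, differential_regulon_expression,
                       discover_programs, discover_states,
                       program_coherence_test)


def _activity(discrete, continuous=None, regulons=None, samples=None):
    discrete = np.asarray(discrete)
    regulons = regulons or [f"r{i}" for i in range(discrete.shape[0])]
    samples = samples or [f"s{j}" for j in range(discrete.shape[1])]
    cont = continuous if continuous is not None else discrete.astype(float)
    return ActivityMatrix(
        discrete=pd.DataFrame(discrete, index=regulons, columns=samples),
        continuous=pd.DataFrame(cont, index=regulons, columns=samples))


class TestDiscoverPrograms:
    def test_identical_activities_share_a_program(self):
        rng = np.random.default_rng(0)
        e = rng.standard_normal(40)
        act = _activity(np.zeros((2, 40)), continuous=np.stack([e, e]))
        programs = discover_programs(act)
        assert len(programs) == 1
        assert set(programs[0].regulon_ids) == {"r0", "r1"}

    def test_anticorrelated_groups_split_into_two_programs(self):
        rng = np.random.default_rng(1)
        e = rng.standard_normal(50)
        cont = np.stack([e + rng.normal(0, 0.2, 50) for _ in range(3)]
                        + [-e + rng.normal(0, 0.2, 50) for _ in range(3)])
        act = _activity(np.zeros((6, 50)), continuous=cont)
        programs = discover_programs(act)
        assert len(programs) == 2
        groups = {frozenset(p.regulon_ids) for p in programs}
        assert groups == {frozenset({"r0", "r1", "r2"}),
                          frozenset({"r3", "r4", "r5"})}

    def test_regulon_order_invariant_up_to_relabeling(self, pipeline):
        act = pipeline.activity
        perm = list(np.random.default_rng(3).permutation(
            act.continuous.index))
        act_perm = ActivityMatrix(discrete=act.discrete.loc[perm],
                                  continuous=act.continuous.loc[perm])
        p1 = {frozenset(p.regulon_ids) for p in discover_programs(act)}
        p2 = {frozenset(p.regulon_ids) for p in discover_programs(act_perm)}
        assert p1 == p2

    def test_member_regulons_covary_positively(self, pipeline):
        programs = discover_programs(pipeline.activity)
        cont = pipeline.activity.continuous
        for p in programs:
            if len(p.regulon_ids) < 2:
                continue
            sub = np.corrcoef(cont.loc[list(p.regulon_ids)].to_numpy())
            m = len(p.regulon_ids)
            assert (sub.sum() - m) / (m * (m - 1)) > 0


class TestDiscoverStates:
    def test_planted_identical_groups_fully_assigned(self):
        base = np.array([[1, -1, 0, 1], [-1, 1, 1, 0], [0, 1, -1, -1]]).T
        discrete = np.concatenate([np.tile(base[:, [k]], (1, 20))
                                   for k in range(3)], axis=1)
        act = _activity(discrete)
        states = discover_states(act)
        assert len(states.state_ids) == 3
        assert states.assigned_fraction == 1.0

    def test_flat_sample_amid_signed_groups_unassigned(self):
        strong = np.concatenate([np.tile([[1]], (8, 20)),
                                 np.tile([[-1]], (8, 20))], axis=1)
        discrete = np.concatenate([strong, np.zeros((8, 1), dtype=int)],
                                  axis=1)
        act = _activity(discrete)
        states = discover_states(act)
        assert states.assignments["s40"] == UNASSIGNED

    def test_duplicated_sample_lands_in_same_state(self, pipeline):
        act = pipeline.activity
        dup = act.discrete.copy()
        dup["twin"] = dup[dup.columns[0]]
        cont = act.continuous.copy()
        cont["twin"] = cont[cont.columns[0]]
        states = discover_states(ActivityMatrix(dup, cont))
        assert (states.assignments["twin"]
                == states.assignments[dup.columns[0]])

    def test_assigned_fraction_monotone_in_threshold(self, pipeline):
        fracs = []
        for thr in (0.3, 0.5, 0.7, 0.9):
            params = Parameters(state_similarity_threshold=thr)
            st = discover_states(pipeline.activity, params)
            fracs.append(st.assigned_fraction)
        assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_planted_states_recovered(self, pipeline):
        states = discover_states(pipeline.activity)
        samples = pipeline.activity.sample_ids
        truth = [pipeline.truth.state_labels[s] for s in samples]
        found = [states.assignments[s] for s in samples]
        assert adjusted_rand_score(truth, found) >= 0.9


class TestDifferentialRegulonExpression:
    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(0)
        eig = pd.DataFrame(rng.standard_normal((200, 40)),
                           index=[f"r{i}" for i in range(200)],
                           columns=[f"s{j}" for j in range(40)])
        res = differential_regulon_expression(
            eig, [f"s{j}" for j in range(20)],
            [f"s{j}" for j in range(20, 40)])
        rate = np.mean([r.significant for r in res])
        assert 0.0 <= rate <= 0.12  # ~5% expected over 200 regulons

    def test_shifted_group_detected_with_direction(self):
        rng = np.random.default_rng(1)
        eig = pd.DataFrame(rng.standard_normal((5, 40)),
                           index=[f"r{i}" for i in range(5)],
                           columns=[f"s{j}" for j in range(40)])
        eig.iloc[0, :20] += 3.0
        res = differential_regulon_expression(
            eig, [f"s{j}" for j in range(20)],
            [f"s{j}" for j in range(20, 40)])
        assert res[0].significant and res[0].direction == 1

    def test_bad_groups_rejected(self, pipeline):
        eig = pipeline.activity.continuous
        with pytest.raises(ValueError, match="non-empty"):
            differential_regulon_expression(eig, [], ["S0000"])
        with pytest.raises(ValueError, match="overlap"):
            differential_regulon_expression(eig, ["S0000"], ["S0000"])


class TestProgramCoherence:
    def test_correlated_program_has_low_variance_p(self, pipeline):
        genes = pipeline.regulons[0].gene_ids
        p = program_coherence_test(pipeline.z, genes, n_perm=200, seed=0)
        assert p < 0.05

    def test_random_gene_sets_reject_at_alpha(self, pipeline):
        rng = np.random.default_rng(2)
        rejections = 0
        n_trials = 100
        for t in range(n_trials):
            genes = rng.choice(pipeline.z.gene_ids, size=12, replace=False)
            p = program_coherence_test(pipeline.z, genes, n_perm=100,
                                       seed=1000 + t)
            rejections += p < 0.05
        assert rejections / n_trials <= 0.12

    def test_degenerate_inputs_rejected(self, pipeline):
        with pytest.raises(ValueError, match="n_perm"):
            program_coherence_test(pipeline.z,
                                   pipeline.regulons[0].gene_ids, n_perm=0)
        with pytest.raises(ValueError, match="2 program genes"):
            program_coherence_test(pipeline.z, ["nope1", "nope2"])
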