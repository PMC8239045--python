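"""Mutation -> regulator -> regulon causal-flow inference.

For every (mutation, regulator) pair the test asks whether mutation carriers
show a coordinated shift of the regulator's expression and of its regulons'
activities beyond what carrier-label permutations produce by chance:

(i)   two-sided rank-sum test of the regulator's expression, carriers vs
      non-carriers (gate: p < 0.05);
(ii)  per-regulon rank-sum tests of the regulon eigengene;
(iii) the statistic S = number of the regulator's regulons that are
      significant AND sign-consistent (sign of the activity shift equals the
      sign of the regulator shift times the regulatory edge sign);
(iv)  an aggregate permutation p-value: the fraction of carrier-count-
      preserving label permutations with a statistic at least as extreme.

Because S is a small integer its permutation distribution is coarse; the
permutation comparison therefore breaks ties in S with a continuous summary
(the summed |z| of the sign-consistent regulons), which keeps the aggregate
test calibrated at its nominal level. An alternative purely continuous
statistic (mean sign-consistent |shift|) is available via ``statistic``.

A regulator and its regulons track the same underlying signal, so gates
(i)-(iv) fire together under chance carrier imbalance; testing every
(mutation, regulator) pair at raw 0.05 would let ~5% of null mutations
through. Emission therefore controls the false discovery rate across all
tested pairs: the regulator association p-values are Benjamini-Hochberg
adjusted jointly across every tested pair (the permutation p-values have a
1/(n_perm+1) resolution floor, so the continuous regulator p carries the
correction; the stricter family-wise Holm adjustment and no correction are
available via ``multiple_testing``). A flow is emitted when the adjusted
regulator p and the raw aggregate permutation p are both < 0.05 with at
least one consistent significant regulon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import rank_matrix, ranksum_p, ranksum_z
from .io import CausalFlow, ExpressionMatrix, MutationMatrix, Program, Regulon
from .params import Parameters

logger = logging.getLogger(__name__)


def test_causal_flow(
    mutations: MutationMatrix,
    expr: ExpressionMatrix,
    regulons: Sequence[Regulon],
    eigengenes: pd.DataFrame,
    params: Optional[Parameters] = None,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    statistic: str = "count",
    multiple_testing: str = "bh",
    return_tests: bool = False,
):
    """Infer causal flows for every sufficiently frequent mutation.

    Mutations below ``params.min_mutation_freq`` carrier frequency are
    skipped (logged). A flow is emitted for a (mutation, regulator) pair when
    the regulator gate holds (rank-sum p < 0.05), at least one regulon is
    significant and sign-consistent, and the aggregate permutation p-value is
    < 0.05. Carrier-label permutations preserve the carrier count exactly;
    permutation p-values use the add-one convention so they are never zero.

    With ``return_tests=True`` also returns a DataFrame with one row per
    tested (mutation, regulator) pair, which is what null-calibration
    analyses consume.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    if statistic not in ("count", "mean_shift"):
        raise ValueError(f"unknown statistic {statistic!r}")
    params = params or Parameters()
    # canonical sample order makes the output independent of column order
    samples = sorted(expr.sample_ids)
    expr_data = expr.data[samples]
    mut = mutations.data[samples]

    regulators = sorted({r.regulator_id for r in regulons})
    regulators = [r for r in regulators if r in expr_data.index]
    reg_to_regulons: dict[str, list[int]] = {r: [] for r in regulators}
    for i, r in enumerate(regulons):
        if r.regulator_id in reg_to_regulons:
            reg_to_regulons[r.regulator_id].append(i)

    eig = eigengenes.loc[[r.regulon_id for r in regulons], samples].to_numpy()
    eig_ranks, eig_ties = rank_matrix(eig)
    reg_expr = expr_data.loc[regulators].to_numpy()
    reg_ranks, reg_ties = rank_matrix(reg_expr)
    edge_signs = np.array([r.edge_sign for r in regulons])
    S_total = len(samples)
    alpha = 0.05

    # shared permutations per carrier count (the null depends only on it);
    # a per-count child seed keeps results independent of mutation order
    perm_cache: dict[int, dict[str, np.ndarray]] = {}

    def null_for(count: int) -> dict[str, np.ndarray]:
        if count not in perm_cache:
            rng = np.random.default_rng([seed, count])
            masks = np.zeros((S_total, n_perm))
            for b in range(n_perm):
                masks[rng.choice(S_total, size=count, replace=False), b] = 1.0
            z_reg = ranksum_z(reg_ranks, reg_ties, masks)       # nreg x P
            z_eig = ranksum_z(eig_ranks, eig_ties, masks)       # nregulon x P
            p_eig = ranksum_p(z_eig)
            perm_cache[count] = {"z_reg": z_reg, "z_eig": z_eig,
                                 "p_eig": p_eig}
        return perm_cache[count]

    def summarize(z_reg_r: np.ndarray, z_eig_m: np.ndarray,
                  p_eig_m: np.ndarray, ridx: np.ndarray):
        """Aggregate statistic per column for one regulator's regulons."""
        shift_sign = np.sign(z_reg_r)                   # (P,) or scalar
        cons = np.sign(z_eig_m[ridx]) == shift_sign * edge_signs[ridx][:, None]
        sig = p_eig_m[ridx] < alpha
        count = (cons & sig).sum(axis=0)
        mag = np.where(cons, np.abs(z_eig_m[ridx]), 0.0).sum(axis=0)
        return count, mag

    flows: list[CausalFlow] = []
    rows = []
    for m_id in mutations.mutation_ids:
        carriers = mut.loc[m_id].to_numpy().astype(bool)
        freq = carriers.mean()
        if freq < params.min_mutation_freq or carriers.sum() == 0:
            logger.info("skipping mutation %s (frequency %.3f)", m_id, freq)
            continue
        if carriers.all():
            logger.info("skipping mutation %s (all samples carriers)", m_id)
            continue
        count = int(carriers.sum())
        null = null_for(count)
        mask = carriers.astype(float)
        z_reg_obs = ranksum_z(reg_ranks, reg_ties, mask)
        p_reg_obs = ranksum_p(z_reg_obs)
        z_eig_obs = ranksum_z(eig_ranks, eig_ties, mask)
        p_eig_obs = ranksum_p(z_eig_obs)
        for gi, regulator in enumerate(regulators):
            ridx = np.array(reg_to_regulons[regulator], dtype=int)
            if ridx.size == 0:
                continue
            c_obs, t_obs = summarize(
                z_reg_obs[gi], z_eig_obs[:, None], p_eig_obs[:, None], ridx)
            c_obs, t_obs = int(c_obs[0]), float(t_obs[0])
            c_perm, t_perm = summarize(
                null["z_reg"][gi], null["z_eig"], null["p_eig"], ridx)
            if statistic == "count":
                more = (c_perm > c_obs) | ((c_perm == c_obs)
                                           & (t_perm >= t_obs))
            else:
                more = t_perm >= t_obs
            agg_p = (1 + int(more.sum())) / (n_perm + 1)
            consistent = (np.sign(z_eig_obs[ridx])
                          == np.sign(z_reg_obs[gi]) * edge_signs[ridx])
            sig = p_eig_obs[ridx] < alpha
            hit = consistent & sig
            affected = tuple(regulons[i].regulon_id
                             for i, h in zip(ridx, hit) if h)
            shift_signs = {regulons[i].regulon_id: int(np.sign(z_eig_obs[i]))
                           for i, h in zip(ridx, hit) if h}
            rows.append({
                "mutation_id": m_id, "regulator_id": regulator,
                "carrier_frequency": freq,
                "regulator_p": float(p_reg_obs[gi]),
                "regulator_sign": int(np.sign(z_reg_obs[gi])),
                "n_regulons": int(ridx.size),
                "n_consistent_significant": c_obs,
                "aggregate_p": agg_p,
                "_affected": affected,
                "_shift_signs": shift_signs,
            })

    tests = pd.DataFrame(rows)
    if len(tests):
        if multiple_testing in ("holm", "bh"):
            from statsmodels.stats.multitest import multipletests
            method = "holm" if multiple_testing == "holm" else "fdr_bh"
            tests["regulator_p_adj"] = multipletests(
                tests["regulator_p"], method=method)[1]
        elif multiple_testing == "none":
            tests["regulator_p_adj"] = tests["regulator_p"]
        else:
            raise ValueError(f"unknown multiple_testing {multiple_testing!r}")
        tests["emitted"] = ((tests["regulator_p_adj"] < alpha)
                            & (tests["n_consistent_significant"] >= 1)
                            & (tests["aggregate_p"] < alpha))
        for row in tests.to_dict("records"):
            if not row["emitted"]:
                continue
            flows.append(CausalFlow(
                mutation_id=row["mutation_id"],
                regulator_id=row["regulator_id"],
                regulon_ids=tuple(row["_affected"]),
                regulator_effect_sign=int(row["regulator_sign"]),
                regulon_shift_signs=dict(row["_shift_signs"]),
                regulator_p=float(row["regulator_p"]),
                aggregate_p=float(row["aggregate_p"]),
                carrier_frequency=float(row["carrier_frequency"]),
            ))
        tests = tests.drop(columns=["_affected", "_shift_signs"])
    if return_tests:
        return flows, tests
    return flows


# the name follows the operation ("test a causal flow"); tell pytest this is
# library code, not a test case
test_causal_flow.__test__ = False


@dataclass
class CausalNetwork:
    """Deduplicated flows plus upstream/downstream indices."""

    flows: list[CausalFlow]
    regulon_upstream: dict[str, tuple[str, ...]]   # regulon -> mutations
    regulator_upstream: dict[str, tuple[str, ...]] # regulator -> mutations
    program_causes: dict[str, tuple[str, ...]]     # program -> mutations
    flow_count: int = 0                            # unique (mut, reg, regulon)


def assemble_causal_network(
    flows: Sequence[CausalFlow],
    regulons: Sequence[Regulon],
    programs: Sequence[Program] = (),
) -> CausalNetwork:
    """Assemble flows into a network fragment with per-node cause indices."""
    regulon_ids = {r.regulon_id for r in regulons}
    regulator_ids = {r.regulator_id for r in regulons}
    seen = set()
    unique_flows = []
    triples = set()
    for f in flows:
        if f.regulator_id not in regulator_ids:
            raise ValueError(f"flow references unknown regulator "
                             f"{f.regulator_id!r}")
        dangling = [rid for rid in f.regulon_ids if rid not in regulon_ids]
        if dangling:
            raise ValueError(f"flow references unknown regulons {dangling}")
        key = (f.mutation_id, f.regulator_id, f.regulon_ids)
        if key in seen:
            continue
        seen.add(key)
        unique_flows.append(f)
        for rid in f.regulon_ids:
            triples.add((f.mutation_id, f.regulator_id, rid))

    regulon_upstream: dict[str, set[str]] = {}
    regulator_upstream: dict[str, set[str]] = {}
    for f in unique_flows:
        regulator_upstream.setdefault(f.regulator_id, set()).add(f.mutation_id)
        for rid in f.regulon_ids:
            regulon_upstream.setdefault(rid, set()).add(f.mutation_id)

    program_causes: dict[str, set[str]] = {}
    for p in programs:
        causes: set[str] = set()
        for rid in p.regulon_ids:
            causes |= regulon_upstream.get(rid, set())
        if causes:
            program_causes[p.program_id] = causes

    return CausalNetwork(
        flows=unique_flows,
        regulon_upstream={k: tuple(sorted(v))
                          for k, v in sorted(regulon_upstream.items())},
        regulator_upstream={k: tuple(sorted(v))
                            for k, v in sorted(regulator_upstream.items())},
        program_causes={k: tuple(sorted(v))
                        for k, v in sorted(program_causes.items())},
        flow_count=len(triples),
    )
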