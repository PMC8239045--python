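"""Synthetic cohorts with planted regulatory structure and ground truth.

The generator emulates the statistical structure of the cohorts this kind of
pipeline is built for: latent regulator activities drive blocks of signed
coexpressed target genes; samples belong to a small number of transcriptional
states that set the baseline of every regulator; binary mutations shift their
target regulator's activity in carriers; progression-free survival follows an
exponential hazard proportional to exp(beta * activity of a designated risk
program), with independent exponential censoring. Decoy genes, decoy
regulators, decoy prior targets and null mutations make every downstream
gate non-trivial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (ExpressionMatrix, GeneSetLibrary, MutationMatrix,
                 SurvivalTable)


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery of the planted structure."""

    regulators: list[str]
    regulons: dict[str, dict]          # planted id -> {regulator, sign, genes}
    mutation_targets: dict[str, str]   # causal mutation -> regulator
    null_mutations: list[str]
    state_labels: dict[str, int]       # sample -> planted state
    state_signatures: np.ndarray       # states x regulators, +/-1
    risk_program_regulator: str
    latents: pd.DataFrame              # regulator x sample latent activity
    generator_params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        doc = {
            "regulators": self.regulators,
            "regulons": self.regulons,
            "mutation_targets": self.mutation_targets,
            "null_mutations": self.null_mutations,
            "state_labels": self.state_labels,
            "state_signatures": self.state_signatures.tolist(),
            "risk_program_regulator": self.risk_program_regulator,
            "latents": {"index": list(self.latents.index),
                        "columns": list(self.latents.columns),
                        "values": self.latents.to_numpy().tolist()},
            "generator_params": self.generator_params,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def simulate_dataset(
    n_samples: int = 300,
    n_regulators: int = 10,
    targets_per_regulator: int = 15,
    n_noise_genes: int = 500,
    noise_sd: float = 0.5,
    n_causal_mutations: int = 10,
    n_null_mutations: int = 90,
    mutation_freq: float = 0.2,
    effect_size: float = 2.0,
    hazard_beta: float = 1.0,
    censor_rate: float = 0.3,
    seed: int = 0,
    n_states: int = 4,
    state_effect: float = 2.0,
    repressed_fraction: float = 0.4,
    decoy_target_fraction: float = 0.2,
    n_decoy_regulators: int = 5,
    counts: bool = False,
) -> tuple[ExpressionMatrix, GeneSetLibrary, MutationMatrix, SurvivalTable,
           SyntheticTruth]:
    """Generate one cohort; the same seed reproduces it bit for bit.

    Planted regulons are the (regulator, sign) target groups:
    ``repressed_fraction`` of each regulator's targets get a -1 edge. Each
    causal mutation adds ``effect_size`` to one regulator's latent activity
    in carriers (exactly round(freq * n) of them). Survival risk follows the
    latent activity of regulator 0 ("the risk program"). With
    ``counts=True`` the expression layer is emitted as negative-binomial
    counts instead of normalized values, for exercising count normalization.
    """
    if min(n_samples, n_regulators, targets_per_regulator) < 1:
        raise ValueError("sizes must be >= 1")
    if not 0 < mutation_freq < 1 or not 0 <= censor_rate < 1:
        raise ValueError("frequencies must be in (0, 1)")
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    regulators = [f"TF{r:02d}" for r in range(n_regulators)]

    # distinct per-state +/-1 regulator signatures: planted states must be
    # mutually distinguishable, so signatures are drawn with a minimum
    # pairwise disagreement of more than half the regulators
    min_sep = n_regulators // 2 + 1 if n_states > 1 else 0
    best_sig, best_d = None, -1
    for _ in range(10000):
        sig = rng.choice([-1.0, 1.0], size=(n_states, n_regulators))
        d = min((int(np.sum(sig[i] != sig[j]))
                 for i in range(n_states) for j in range(i + 1, n_states)),
                default=n_regulators)
        if d > best_d:
            best_sig, best_d = sig, d
        if d >= min_sep:
            break
    signatures = best_sig
    state_of = rng.integers(n_states, size=n_samples)

    latent = (state_effect * signatures[state_of].T
              + rng.standard_normal((n_regulators, n_samples)))

    # causal mutations: one regulator each, exact carrier counts
    n_carriers = int(round(mutation_freq * n_samples))
    causal_ids = [f"MUT_C{m:02d}" for m in range(n_causal_mutations)]
    null_ids = [f"MUT_N{m:02d}" for m in range(n_null_mutations)]
    mutation_targets = {m: regulators[i % n_regulators]
                        for i, m in enumerate(causal_ids)}
    mut = pd.DataFrame(0, index=causal_ids + null_ids, columns=samples,
                       dtype=int)
    for m in causal_ids:
        carriers = rng.choice(n_samples, size=n_carriers, replace=False)
        mut.loc[m, np.array(samples)[carriers]] = 1
        ridx = regulators.index(mutation_targets[m])
        latent[ridx, carriers] += effect_size
    for m in null_ids:
        carriers = rng.choice(n_samples, size=n_carriers, replace=False)
        mut.loc[m, np.array(samples)[carriers]] = 1

    # signed target genes and planted regulons
    n_rep = int(round(repressed_fraction * targets_per_regulator))
    gene_rows = {}
    regulon_truth: dict[str, dict] = {}
    for r, reg in enumerate(regulators):
        gene_rows[reg] = latent[r] + rng.normal(0, noise_sd / 2, n_samples)
        names = [f"G_{reg}_{t:02d}" for t in range(targets_per_regulator)]
        signs = [-1] * n_rep + [1] * (targets_per_regulator - n_rep)
        for name, sign in zip(names, signs):
            gene_rows[name] = (sign * latent[r]
                               + rng.normal(0, noise_sd, n_samples))
        for sign, tag in ((1, "act"), (-1, "rep")):
            members = [n for n, s in zip(names, signs) if s == sign]
            if members:
                regulon_truth[f"{reg}_{tag}"] = {
                    "regulator": reg, "sign": sign, "genes": members}

    noise_names = [f"N{i:04d}" for i in range(n_noise_genes)]
    for name in noise_names:
        gene_rows[name] = rng.standard_normal(n_samples)

    expr_df = pd.DataFrame(gene_rows, index=samples).T  # genes x samples

    # prior: true targets plus decoy targets, plus decoy regulators
    n_decoy_targets = min(int(round(decoy_target_fraction
                                    * targets_per_regulator)), n_noise_genes)
    n_decoy_regulators = min(n_decoy_regulators, n_noise_genes)
    sets = {}
    for reg in regulators:
        true_targets = [n for rt in regulon_truth.values()
                        if rt["regulator"] == reg for n in rt["genes"]]
        decoys = list(rng.choice(noise_names, size=n_decoy_targets,
                                 replace=False)) if n_decoy_targets else []
        sets[reg] = frozenset(true_targets + decoys)
    decoy_pool = noise_names[n_decoy_regulators:]
    for d in range(n_decoy_regulators):
        name = noise_names[d]  # decoy regulators are measured noise genes
        targets = rng.choice(decoy_pool,
                             size=min(targets_per_regulator, len(decoy_pool)),
                             replace=False)
        if len(targets):
            sets[name] = frozenset(targets)
    prior = GeneSetLibrary(sets, source_name="synthetic-binding-sites")

    # survival: exponential hazard on the designated risk program's activity
    risk_activity = latent[0]
    rates = np.exp(hazard_beta * (risk_activity - risk_activity.mean()))
    rates *= 1.0 / 365.0  # baseline scale: median PFS on the order of a year
    event_times = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        def mean_censored(lam):
            return np.mean(lam / (lam + rates)) - censor_rate
        lam_c = brentq(mean_censored, 1e-12, 1e3)
        censor_times = rng.exponential(1.0 / lam_c, size=n_samples)
    else:
        censor_times = np.full(n_samples, np.inf)
    observed = np.minimum(event_times, censor_times)
    events = event_times <= censor_times
    survival = SurvivalTable(pd.DataFrame({
        "sample_id": samples,
        "duration": np.maximum(observed, 1e-3),
        "event": events,
    }))

    if counts:
        # negative-binomial count layer over the latent expression
        base = rng.lognormal(mean=4.0, sigma=1.0, size=expr_df.shape[0])
        depth = rng.lognormal(mean=0.0, sigma=0.25, size=n_samples)
        mu = base[:, None] * np.exp(0.5 * expr_df.to_numpy()) * depth[None, :]
        dispersion = 0.3
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
        expr_df = pd.DataFrame(rng.poisson(lam).astype(float),
                               index=expr_df.index, columns=expr_df.columns)
        expr = ExpressionMatrix(expr_df, state="counts")
    else:
        expr = ExpressionMatrix(expr_df, state="normalized")

    truth = SyntheticTruth(
        regulators=regulators,
        regulons=regulon_truth,
        mutation_targets=mutation_targets,
        null_mutations=null_ids,
        state_labels={s: int(z) for s, z in zip(samples, state_of)},
        state_signatures=signatures,
        risk_program_regulator=regulators[0],
        latents=pd.DataFrame(latent, index=regulators, columns=samples),
        generator_params={
            "n_samples": n_samples, "n_regulators": n_regulators,
            "targets_per_regulator": targets_per_regulator,
            "n_noise_genes": n_noise_genes, "noise_sd": noise_sd,
            "n_causal_mutations": n_causal_mutations,
            "n_null_mutations": n_null_mutations,
            "mutation_freq": mutation_freq, "effect_size": effect_size,
            "hazard_beta": hazard_beta, "censor_rate": censor_rate,
            "seed": seed, "n_states": n_states,
            "state_effect": state_effect,
            "repressed_fraction": repressed_fraction,
            "decoy_target_fraction": decoy_target_fraction,
            "n_decoy_regulators": n_decoy_regulators, "counts": counts,
        })
    return expr, prior, MutationMatrix(mut), survival, truth
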