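# regulonet

Causal-mechanistic transcriptional regulatory network (TRN) inference for
patient cohorts with matched expression, mutation and survival data —
built for the kind of bulk RNA-seq cancer cohorts (hundreds of patients,
binary mutation/translocation calls, censored progression-free survival)
where the question is not just *who* is high-risk but *which regulatory
mechanisms make them so*.

From a gene × sample expression matrix, a regulator → targets binding-site
prior (GMT/JSON), a binary mutation × sample matrix and a clinical table,
`regulonet` infers:

- **regulons** — co-expressed gene sets sharing a binding site for one
  regulator R, with a signed edge: enrichment p < 0.05 (hypergeometric),
  ≥ 5 genes, |corr(R, eigengene)| ≥ 0.2, where the *eigengene* is the first
  principal component of the member genes;
- **discrete per-sample activity** — per sample, genes are ranked into
  thirds; a regulon with k of N genes in the top third is called
  overexpressed when the exact binomial tail P(X ≥ k | N, p = 1/3) < 0.05
  (underexpressed symmetrically), giving a {−1, 0, +1} matrix;
- **programs and transcriptional states** — clusters of regulons with
  similar activity, and clusters of patients with similar network-wide
  activity (samples matching no state stay unassigned);
- **causal flows** — mutation → regulator → regulon chains in which
  carriers shift the regulator and its regulons coherently beyond what
  carrier-label permutations produce (statistic: the count of significant,
  sign-consistent regulons; add-one permutation p-values; emission under
  cross-pair multiple-testing control);
- **network activity** — each gene's expression corrected toward the
  sign-adjusted consensus of the regulons containing it;
- **TF–TF networks** — prior-restricted LASSO regressions, backward-pruned
  on held-out R²;
- **survival risk** — GuanRank converts censored survival into a [0,1]
  risk rank by pairwise comparison; Ridge regression of GuanRank on regulon
  activity (trained on the clearly high/low-risk extremes, penalty chosen
  by repeated-split AUC) predicts risk for every patient, with univariate
  Cox hazard ratios and AUC-based feature-space comparisons alongside;
- **benchmarks** — any regulon set (including an external tool's) scored on
  coherence, binding-site enrichment, and topology preservation (Spearman
  correlation of pairwise sample distances in expression vs activity space).

A seeded synthetic-cohort generator with planted regulons, states, causal
mutations and survival effects provides ground truth for every stage.
See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
import pandas as pd
from regulonet import (simulate_dataset, zscore_genes, cluster_coexpression,
                       infer_regulons, discrete_regulon_activity,
                       discover_programs, discover_states, test_causal_flow,
                       guanrank, fit_risk_model, evaluate_risk)

expr, prior, mutations, survival, truth = simulate_dataset(seed=1)
z = zscore_genes(expr)
clusters, _ = cluster_coexpression(z, seed=1)
regulons = infer_regulons(clusters, prior, z)
print(f"{len(regulons)} regulons from {len(clusters)} coexpression clusters")

activity = discrete_regulon_activity(expr, regulons)
states = discover_states(activity)
programs = discover_programs(activity)
print(f"{len(programs)} programs, {len(states.state_ids)} states "
      f"({states.assigned_fraction:.0%} of samples assigned)")

flows = test_causal_flow(mutations, expr, regulons, activity.continuous,
                         n_perm=1000, seed=1)
print(f"{len(flows)} causal flows, e.g. "
      f"{flows[0].mutation_id} -> {flows[0].regulator_id} -> "
      f"{len(flows[0].regulon_ids)} regulons "
      f"(aggregate p = {flows[0].aggregate_p:.2g})")

scores = guanrank(survival)
model = fit_risk_model(activity.discrete.T, scores, seed=1)
preds = pd.Series(model.predict(activity.discrete.T),
                  index=activity.discrete.columns)
print(f"risk model: alpha = {model.alpha_}, "
      f"held-out AUC = {model.cv_mean_auc_:.2f}, "
      f"full-cohort AUC = {evaluate_risk(preds, scores):.2f}")
```

prints

```text
20 regulons from 10 coexpression clusters
14 programs, 4 states (99% of samples assigned)
12 causal flows, e.g. MUT_C00 -> TF00 -> 2 regulons (aggregate p = 0.001)
risk model: alpha = 31.622776601683793, held-out AUC = 0.96, full-cohort AUC = 0.85
```

The cohort planted 10 regulators × 15 signed targets: the 20 inferred
regulons are the activated and repressed target groups of each regulator;
the 4 recovered states are the 4 planted patient subtypes; the causal flows
point each planted mutation at its true regulator (p = 0.001 is the
permutation floor at 1000 permutations); and the held-out AUC of 0.96
reflects the planted hazard acting through regulator-0 activity.
The full-cohort AUC (0.85) is lower because it scores *all* patients,
including the censored middle-risk band excluded from training.

The same steps run from a shell via the `regulonet` CLI
(`simulate`, `normalize`, `infer`, `activity`, `programs`, `states`,
`causal`, `tfnet`, `risk`, `benchmark`, `overlap`), and real cohorts enter
through `read_expression_matrix`, `read_gene_set_library`,
`read_mutation_matrix` and `read_clinical_table`. Pre-normalized validation
matrices (e.g. z-scored microarray exports) are accepted as-is, and
`discrete_regulon_activity(..., allow_missing=True)` scores a trained
network on platforms that lack some member genes.

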