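"""Pipeline-wide tunable parameters with their defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class Parameters:
    """Defaults for every threshold used across the pipeline.

    The gates that define a regulon (size >= 5 genes, binding-site enrichment
    p < 0.05, |regulator-eigengene correlation| >= 0.2, coexpressed cluster
    size >= 6) and the downstream testing parameters (tertile binomial alpha,
    2% minimum mutation carrier frequency, permutation and repeat counts,
    risk-labelling fractions) are all collected here so a single object can be
    passed through the pipeline and serialized with a network bundle.
    """

    min_cluster_genes: int = 6
    min_regulon_genes: int = 5
    min_abs_regulator_corr: float = 0.2
    max_enrichment_p: float = 0.05
    activity_alpha: float = 0.05
    tertile_null_p: float = 1.0 / 3.0
    min_mutation_freq: float = 0.02
    coherence_permutations: int = 500
    ridge_repeats: int = 500
    split_repeats: int = 100
    highrisk_train_frac: float = 0.20
    lowrisk_train_frac: float = 0.50
    highrisk_label_frac: float = 0.20
    subtype_highrisk_frac: float = 0.30
    # concretization knobs (the source method names no algorithm for these)
    cluster_cut_height: float = 0.5
    cluster_filter_permutations: int = 100
    program_cut_height: float = 0.3
    state_similarity_threshold: float = 0.5
    min_state_size: int = 5
    tf_prune_tolerance: float = 0.01
    causal_n_perm: int = 1000
    dominance_top_k: int = 10
    trim_fraction: float = 0.05
    bh_correction: bool = False

    def __post_init__(self) -> None:
        for name in (
            "min_abs_regulator_corr",
            "max_enrichment_p",
            "activity_alpha",
            "tertile_null_p",
            "min_mutation_freq",
            "highrisk_train_frac",
            "lowrisk_train_frac",
            "highrisk_label_frac",
            "subtype_highrisk_frac",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in (
            "min_cluster_genes",
            "min_regulon_genes",
            "coherence_permutations",
            "ridge_repeats",
            "split_repeats",
            "causal_n_perm",
            "min_state_size",
        ):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kwargs) -> "Parameters":
        return dataclasses.replace(self, **kwargs)
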