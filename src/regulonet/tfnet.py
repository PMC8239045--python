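"""Prior-restricted TF-TF network inference by L1 regression.

For every target TF the candidate predictors are the listed TFs that carry a
binding site for the target in the prior. An L1-penalized (LASSO) model is
fit with cross-validated penalty selection, then backward-pruned: the
smallest-|coefficient| predictor is dropped while the held-out R-squared
stays within a tolerance of the unpruned model. Surviving nonzero
coefficients become weighted directed edges.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold, cross_val_score

from .io import ExpressionMatrix, GeneSetLibrary, TFEdge
from .params import Parameters

logger = logging.getLogger(__name__)


def _holdout_r2(X: np.ndarray, y: np.ndarray, alpha: float,
                cv: KFold) -> float:
    model = Lasso(alpha=alpha, max_iter=10000)
    return float(np.mean(cross_val_score(model, X, y, cv=cv, scoring="r2")))


def infer_tf_tf_network(
    tf_list: Sequence[str],
    expr: ExpressionMatrix,
    prior: GeneSetLibrary,
    params: Optional[Parameters] = None,
    seed: int = 0,
    chip_prior: Optional[GeneSetLibrary] = None,
) -> list[TFEdge]:
    """Infer weighted TF->TF edges restricted to binding-site-backed pairs.

    ``chip_prior`` (e.g. ChIP-seq derived targets), when given, is merged
    with the binding-site prior by union.
    """
    params = params or Parameters()
    tf_list = list(dict.fromkeys(tf_list))
    missing = [t for t in tf_list if t not in expr.data.index]
    if missing:
        raise ValueError(f"TFs absent from expression matrix: {missing}")

    def targets_of(source: str) -> frozenset:
        base = prior[source] if source in prior else frozenset()
        if chip_prior is not None and source in chip_prior:
            base = base | chip_prior[source]
        return base

    data = expr.data
    edges: list[TFEdge] = []
    rng = np.random.default_rng(seed)
    for target in tf_list:
        candidates = [s for s in tf_list
                      if s != target and target in targets_of(s)]
        if not candidates:
            logger.info("no prior-backed predictors for %s", target)
            continue
        X = data.loc[candidates].to_numpy().T       # samples x predictors
        y = data.loc[target].to_numpy()
        # standardize so the L1 penalty treats predictors comparably
        Xs = (X - X.mean(0)) / np.where(X.std(0) > 1e-12, X.std(0), 1.0)
        ys_sd = y.std() if y.std() > 1e-12 else 1.0
        ys = (y - y.mean()) / ys_sd
        cv = KFold(n_splits=5, shuffle=True,
                   random_state=int(rng.integers(2**31 - 1)))
        lcv = LassoCV(cv=cv, max_iter=10000)
        lcv.fit(Xs, ys)
        alpha = float(lcv.alpha_)
        active = [i for i, c in enumerate(lcv.coef_) if c != 0.0]
        if not active:
            continue
        base_r2 = _holdout_r2(Xs[:, active], ys, alpha, cv)
        # backward pruning on held-out accuracy
        coefs = {i: lcv.coef_[i] for i in active}
        while len(active) > 1:
            drop = min(active, key=lambda i: abs(coefs[i]))
            trial = [i for i in active if i != drop]
            r2 = _holdout_r2(Xs[:, trial], ys, alpha, cv)
            if r2 >= base_r2 - params.tf_prune_tolerance:
                active = trial
                m = Lasso(alpha=alpha, max_iter=10000).fit(Xs[:, active], ys)
                coefs = dict(zip(active, m.coef_))
            else:
                break
        # a model with no held-out predictive power defines no edges
        if _holdout_r2(Xs[:, active], ys, alpha, cv) <= 0.0:
            logger.info("pruned model for %s has no held-out accuracy; "
                        "no edges", target)
            continue
        final = Lasso(alpha=alpha, max_iter=10000).fit(Xs[:, active], ys)
        for i, c in zip(active, final.coef_):
            if c != 0.0:
                edges.append(TFEdge(source_tf=candidates[i],
                                    target_tf=target, weight=float(c)))
    return edges


def out_degree(edges: Sequence[TFEdge]) -> dict[str, int]:
    """Simple master-regulator summary: outgoing edge counts per TF."""
    counts: dict[str, int] = {}
    for e in edges:
        counts[e.source_tf] = counts.get(e.source_tf, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
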