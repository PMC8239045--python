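"""Censored-survival risk ranking and network-based risk prediction.

GuanRank converts censored progression-free survival into a normalized [0,1]
risk score per patient by pairwise comparison: patient i collects one point
for every patient j that i is unambiguously at higher risk than (an observed
progression at or before j's event or censoring time), half a point for every
ambiguous or tied pair (both censored, or an event after the other's
censoring), and zero otherwise; raw scores are min-max normalized.

Risk models are L2-penalized (Ridge) regressions of GuanRank on regulon
activity, trained only on the clearly high-risk (top 20%) and clearly
low-risk (bottom 50%) patients, with the penalty chosen to maximize the mean
held-out AUC over repeated random splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.utils.validation import check_is_fitted

from .io import SurvivalTable
from .params import Parameters

logger = logging.getLogger(__name__)


def guanrank(survival: SurvivalTable) -> pd.Series:
    """Normalized pairwise risk rank in [0, 1]; 1 is the highest risk.

    With no censoring this reduces to the reversed, min-max-normalized rank
    of event time.
    """
    if len(survival) < 2:
        raise ValueError("guanrank needs at least 2 samples")
    t = survival.durations
    e = survival.events
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None], e[None, :]
    s = np.full((len(t), len(t)), 0.5)
    # i event vs j event: strict earlier event is higher risk; tie -> 0.5
    s = np.where(ei & ej & (ti < tj), 1.0, s)
    s = np.where(ei & ej & (ti > tj), 0.0, s)
    # i event vs j censored: certain iff the event precedes the censoring
    s = np.where(ei & ~ej & (ti <= tj), 1.0, s)
    # i censored vs j event: j is certainly higher risk iff t_j <= c_i
    s = np.where(~ei & ej & (tj <= ti), 0.0, s)
    np.fill_diagonal(s, 0.0)
    raw = s.sum(axis=1)
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        raw = (raw - lo) / (hi - lo)
    else:
        raw = np.zeros_like(raw)
    return pd.Series(raw, index=survival.sample_ids)


def high_risk_labels(scores: pd.Series, label_frac: float = 0.20) -> pd.Series:
    """Binary labels marking the top ``label_frac`` of scores as high risk."""
    n_high = max(1, int(round(label_frac * len(scores))))
    order = scores.sort_values(ascending=False, kind="mergesort")
    labels = pd.Series(False, index=scores.index)
    labels[order.index[:n_high]] = True
    return labels


def _feature_auc_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column AUC of X against binary y, via rank sums (fast, tie-aware)."""
    from scipy.stats import rankdata
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(X, axis=0, method="average")
    r1 = ranks[y.astype(bool)].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


class GuanRankRidge(BaseEstimator, RegressorMixin):
    """Ridge regression of GuanRank on activity features, extremes-only training.

    Parameters
    ----------
    alphas : regularization grid (default 13 log-spaced values 1e-3..1e3).
    n_repeats : random train/test splits used to pick the penalty by mean AUC.
    highrisk_train_frac, lowrisk_train_frac : extremes kept for training.
    label_frac : top fraction labeled high-risk for AUC computation.

    Fitted attributes: ``alpha_``, ``coef_``, ``intercept_``,
    ``cv_mean_auc_`` (held-out mean AUC at the selected penalty),
    ``cv_results_``, ``training_samples_``.
    """

    def __init__(self, alphas: Optional[Sequence[float]] = None,
                 n_repeats: int = 500, test_size: float = 0.2,
                 highrisk_train_frac: float = 0.20,
                 lowrisk_train_frac: float = 0.50,
                 label_frac: float = 0.20,
                 random_state: int = 0):
        self.alphas = alphas
        self.n_repeats = n_repeats
        self.test_size = test_size
        self.highrisk_train_frac = highrisk_train_frac
        self.lowrisk_train_frac = lowrisk_train_frac
        self.label_frac = label_frac
        self.random_state = random_state

    def _grid(self) -> np.ndarray:
        if self.alphas is not None:
            return np.asarray(self.alphas, dtype=float)
        return np.logspace(-3, 3, 13)

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        n = len(y)
        order = y.sort_values(ascending=False, kind="mergesort").index
        n_high = max(1, int(round(self.highrisk_train_frac * n)))
        n_low = max(1, int(round(self.lowrisk_train_frac * n)))
        # canonical ordering of the training subset: the fitted model then
        # does not depend on the incoming sample order
        train_idx = pd.Index(sorted(order[:n_high].append(order[n - n_low:])))
        if len(train_idx) < 10:
            raise ValueError("fewer than 10 training samples after "
                             "extremes selection")
        Xt = X.loc[train_idx].to_numpy()
        yt = y.loc[train_idx].to_numpy()
        labels = high_risk_labels(y, self.label_frac).loc[train_idx].to_numpy()

        grid = self._grid()
        splitter = StratifiedShuffleSplit(
            n_splits=self.n_repeats, test_size=self.test_size,
            random_state=self.random_state)
        aucs = np.zeros((len(grid), self.n_repeats))
        for rep, (tr, te) in enumerate(splitter.split(Xt, labels)):
            if labels[te].all() or not labels[te].any():
                aucs[:, rep] = np.nan
                continue
            for a, alpha in enumerate(grid):
                model = Ridge(alpha=alpha).fit(Xt[tr], yt[tr])
                pred = model.predict(Xt[te])
                aucs[a, rep] = roc_auc_score(labels[te], pred)
        mean_auc = np.nanmean(aucs, axis=1)
        best = int(np.argmax(mean_auc))
        self.alpha_ = float(grid[best])
        self.cv_mean_auc_ = float(mean_auc[best])
        self.cv_results_ = pd.DataFrame(
            {"alpha": grid, "mean_auc": mean_auc})
        final = Ridge(alpha=self.alpha_).fit(Xt, yt)
        self.coef_ = final.coef_
        self.intercept_ = float(final.intercept_)
        self.feature_ids_ = list(X.columns)
        self.training_samples_ = list(train_idx)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_ids_]
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def fit_risk_model(features: pd.DataFrame, scores: pd.Series,
                   params: Optional[Parameters] = None,
                   seed: int = 0) -> GuanRankRidge:
    """Fit the default risk model on a features (samples x regulons) frame."""
    params = params or Parameters()
    common = [s for s in features.index if s in scores.index]
    model = GuanRankRidge(
        n_repeats=params.ridge_repeats,
        highrisk_train_frac=params.highrisk_train_frac,
        lowrisk_train_frac=params.lowrisk_train_frac,
        label_frac=params.highrisk_label_frac,
        random_state=seed)
    return model.fit(features.loc[common], scores.loc[common])


def evaluate_risk(predictions: pd.Series, scores: pd.Series,
                  label_frac: float = 0.20) -> float:
    """AUC of predictions against binary top-``label_frac`` risk labels."""
    common = predictions.index.intersection(scores.index)
    labels = high_risk_labels(scores.loc[common], label_frac)
    if labels.all() or not labels.any():
        raise ValueError("one risk class is empty")
    return float(roc_auc_score(labels.to_numpy(),
                               predictions.loc[common].to_numpy()))


@dataclass
class CoxResult:
    covariate_id: str
    hazard_ratio: float
    p_value: float
    n: int


def cox_univariate(values: pd.Series, survival: SurvivalTable,
                   name: str = "x") -> CoxResult:
    """Single-covariate Cox proportional-hazards fit (Efron tie handling)."""
    from lifelines import CoxPHFitter

    tab = survival.table.set_index("sample_id")
    common = [s for s in values.index if s in tab.index]
    x = values.loc[common].to_numpy(dtype=float)
    if np.std(x) <= 1e-12:
        raise ValueError("constant covariate")
    df = pd.DataFrame({
        "duration": tab.loc[common, "duration"].to_numpy(),
        "event": tab.loc[common, "event"].to_numpy().astype(int),
        name: x,
    })
    cph = CoxPHFitter()
    cph.fit(df, duration_col="duration", event_col="event")
    return CoxResult(
        covariate_id=name,
        hazard_ratio=float(np.exp(cph.params_[name])),
        p_value=float(cph.summary.loc[name, "p"]),
        n=len(df))


@dataclass
class FeatureSpaceComparison:
    """Paired per-split test AUCs for two feature spaces on identical splits."""

    auc_expression: np.ndarray
    auc_network: np.ndarray

    @property
    def mean_expression(self) -> float:
        return float(np.mean(self.auc_expression))

    @property
    def mean_network(self) -> float:
        return float(np.mean(self.auc_network))

    def paired_p(self) -> float:
        """One-sided paired Wilcoxon p that network beats expression."""
        from scipy.stats import wilcoxon
        diff = self.auc_network - self.auc_expression
        if np.allclose(diff, 0):
            return 1.0
        return float(wilcoxon(self.auc_network, self.auc_expression,
                              alternative="greater").pvalue)


def _best_feature_auc(train_X, train_y, test_X, test_y) -> float:
    """Pick the single best risk-stratifying feature on train, score on test.

    Feature orientation (risk-increasing vs risk-decreasing) is chosen on
    the training split and applied unchanged to the test split.
    """
    aucs = _feature_auc_matrix(train_X, train_y)
    oriented = np.maximum(aucs, 1.0 - aucs)
    best = int(np.argmax(oriented))
    flip = aucs[best] < 0.5
    test_auc = _feature_auc_matrix(test_X[:, [best]], test_y)[0]
    return float(1.0 - test_auc if flip else test_auc)


def compare_feature_spaces(
    expr_features: pd.DataFrame,
    network_features: pd.DataFrame,
    scores: pd.Series,
    subtype_samples: Sequence[str],
    params: Optional[Parameters] = None,
    seed: int = 0,
    test_size: float = 0.3,
) -> FeatureSpaceComparison:
    """Single-best-gene risk AUC distributions: expression vs network activity.

    Within the given subtype the top ``subtype_highrisk_frac`` (default 30%)
    of patients by GuanRank are labeled truly high risk; each repetition
    draws one stratified train/test split shared by both feature spaces,
    picks the best train-split feature in each space, and records its test
    AUC.
    """
    params = params or Parameters()
    samples = [s for s in subtype_samples
               if s in expr_features.index and s in scores.index]
    if len(samples) < 20:
        raise ValueError("subtype needs at least 20 samples")
    y = high_risk_labels(scores.loc[samples],
                         params.subtype_highrisk_frac).to_numpy()
    Xe = expr_features.loc[samples].to_numpy()
    Xn = network_features.loc[samples].to_numpy()
    splitter = StratifiedShuffleSplit(n_splits=params.split_repeats,
                                      test_size=test_size, random_state=seed)
    auc_e, auc_n = [], []
    for tr, te in splitter.split(Xe, y):
        auc_e.append(_best_feature_auc(Xe[tr], y[tr], Xe[te], y[te]))
        auc_n.append(_best_feature_auc(Xn[tr], y[tr], Xn[te], y[te]))
    return FeatureSpaceComparison(np.array(auc_e), np.array(auc_n))


@dataclass
class UnivariateScreenResult:
    intersection: tuple[str, ...]
    top_expression: tuple[str, ...]
    top_network: tuple[str, ...]
    holdout_aucs: Optional[pd.Series] = None
    permuted_reference_auc: Optional[float] = None


def univariate_screen(
    expr_features: pd.DataFrame,
    network_features: pd.DataFrame,
    scores: pd.Series,
    top_n: int = 100,
    label_frac: float = 0.20,
    holdout: Optional[tuple[pd.DataFrame, pd.Series]] = None,
    seed: int = 0,
) -> UnivariateScreenResult:
    """Intersect the top risk-stratifying genes of two feature spaces.

    Genes are ranked by orientation-corrected AUC against the top
    ``label_frac`` high-risk labels in each space; the intersection of the
    two top-``top_n`` lists is evaluated per gene in a held-out cohort, with
    permuted feature values providing the chance reference.
    """
    genes = [g for g in expr_features.columns
             if g in network_features.columns]
    if top_n > len(genes):
        raise ValueError(f"top_n={top_n} exceeds {len(genes)} shared genes")
    samples = [s for s in expr_features.index if s in scores.index]
    y = high_risk_labels(scores.loc[samples], label_frac).to_numpy()

    def top_genes(feat: pd.DataFrame) -> list[str]:
        X = feat.loc[samples, genes].to_numpy()
        aucs = _feature_auc_matrix(X, y)
        oriented = np.maximum(aucs, 1.0 - aucs)
        order = np.argsort(-oriented, kind="mergesort")
        return [genes[i] for i in order[:top_n]]

    top_e = top_genes(expr_features)
    top_nw = top_genes(network_features)
    inter = tuple(sorted(set(top_e) & set(top_nw)))

    holdout_aucs = None
    ref_auc = None
    if holdout is not None and inter:
        h_feat, h_scores = holdout
        h_samples = [s for s in h_feat.index if s in h_scores.index]
        hy = high_risk_labels(h_scores.loc[h_samples], label_frac).to_numpy()
        present = [g for g in inter if g in h_feat.columns]
        H = h_feat.loc[h_samples, present].to_numpy()
        aucs = _feature_auc_matrix(H, hy)
        holdout_aucs = pd.Series(aucs, index=present)
        rng = np.random.default_rng(seed)
        perm = H.copy()
        for j in range(perm.shape[1]):
            rng.shuffle(perm[:, j])
        ref_auc = float(np.mean(_feature_auc_matrix(perm, hy)))
    return UnivariateScreenResult(
        intersection=inter, top_expression=tuple(top_e),
        top_network=tuple(top_nw), holdout_aucs=holdout_aucs,
        permuted_reference_auc=ref_auc)
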