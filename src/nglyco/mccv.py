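"""Monte Carlo cross-validated SVM biomarker models.

Each MCCV run draws a balanced subsample (equal numbers per class,
without replacement), uses two-thirds of it to rank trait importances
(absolute weights of a linear SVM on standardized traits) and to fit one
SVM per candidate model size on the top-ranked traits, and evaluates class
probabilities (logistic calibration of the SVM decision values, fitted on
the training fold) on the held-out third.  Across runs the per-sample
held-out probabilities are averaged; the averaged ROC/AUC and the
predictive accuracy at the probability boundary 0.5 summarize each model
size.  Because the subsampling is balanced, 0.5 is the natural decision
boundary of the averaged probability.

Feature ranking happens inside every run, strictly before validation, so
no information leaks from the held-out third into the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc, roc_curve
from sklearn.svm import SVC

__all__ = ["MccvConfig", "ModelSweepResult", "FittedModel", "rank_features",
           "feature_importances",
           "mccv_evaluate", "average_roc", "fit_final_model", "apply_model"]


@dataclass(frozen=True)
class MccvConfig:
    n_runs: int = 100
    train_fraction: float = 2.0 / 3.0
    model_sizes: tuple | None = None     # default: {2, 3, 5, 8} capped at p, plus p
    C: float = 1.0
    kernel: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 10:
            raise ValueError("need at least 10 MCCV runs")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must be in (0, 1)")
        if self.model_sizes is not None and any(s < 2 for s in self.model_sizes):
            raise ValueError("model sizes must be >= 2")

    def sizes_for(self, p: int) -> tuple:
        if self.model_sizes is not None:
            sizes = tuple(s for s in self.model_sizes if s <= p)
        else:
            base = {s for s in (2, 3, 5, 8) if s <= p}
            if 2 <= p <= 8:
                base.add(p)
            sizes = tuple(sorted(base))
        if not sizes:
            raise ValueError("need at least 2 candidate traits")
        return sizes


@dataclass
class ModelSweepResult:
    sizes: tuple
    auc: dict                        # size -> averaged-probability AUC
    accuracy: dict                   # size -> accuracy at the 0.5 boundary
    roc: dict                        # size -> (fpr, tpr)
    avg_probability: pd.DataFrame    # samples x sizes, mean held-out P(positive)
    selection_frequency: pd.DataFrame  # traits x sizes
    mean_importance_rank: pd.Series  # across runs (1 = most important)
    best_size: int
    positive_label: object
    n_runs: int
    excluded_samples: list = field(default_factory=list)


def _univariate_auc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column |AUC - 0.5| used only to break importance ties."""
    out = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        fpr, tpr, _ = roc_curve(y, x[:, j])
        out[j] = abs(sk_auc(fpr, tpr) - 0.5)
    return out


def feature_importances(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> np.ndarray:
    """Per-trait importance: absolute weight of a linear SVM on standardized
    traits."""
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    svc = SVC(kernel="linear", C=C)
    svc.fit(X, y)
    return np.abs(np.asarray(svc.coef_).ravel())


def rank_features(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> np.ndarray:
    """Importance order (best first) from absolute linear-SVM weights.

    ``X`` must already be standardized.  Ties are broken by the per-trait
    univariate AUC and then by column order.
    """
    importance = feature_importances(X, y, C)
    uni = _univariate_auc(X, y)
    # lexsort: last key is primary; negative for descending
    return np.lexsort((np.arange(X.shape[1]), -uni, -importance))


def _canonical_classes(labels: np.ndarray, positive=None):
    """Class pair ordered by first occurrence (label-name independent for
    the random-number stream), plus the positive label for reporting."""
    seen = []
    for v in labels:
        if v not in seen:
            seen.append(v)
        if len(seen) == 2:
            break
    if len(seen) < 2:
        raise ValueError("need two classes")
    if positive is None:
        positive = sorted(map(str, seen))[-1]
        positive = next(v for v in seen if str(v) == positive)
    return seen, positive


def mccv_evaluate(traits: pd.DataFrame, labels: pd.Series,
                  config: MccvConfig = MccvConfig(),
                  positive=None) -> ModelSweepResult:
    """Run the balanced MCCV model-size sweep.

    ``traits`` is samples x traits; missing values are imputed with the
    training-fold mean inside each run.  Deterministic under a fixed
    ``config.seed``.
    """
    labels = pd.Series(labels).reindex(traits.index)
    y_all = labels.to_numpy()
    classes, positive = _canonical_classes(y_all, positive)
    idx_by_class = [np.flatnonzero(y_all == c) for c in classes]
    n_bal = min(len(i) for i in idx_by_class)
    n_tr = int(round(config.train_fraction * n_bal))
    n_tr = min(max(n_tr, 1), n_bal - 1)
    if n_bal < 6:
        raise ValueError(f"balanced MCCV needs at least 6 samples per class, "
                         f"got {n_bal}")
    X_all = traits.to_numpy(dtype=float)
    n, p = X_all.shape
    sizes = config.sizes_for(p)
    rng = np.random.default_rng(config.seed)

    prob_sum = {k: np.zeros(n) for k in sizes}
    prob_cnt = {k: np.zeros(n) for k in sizes}
    sel_cnt = {k: np.zeros(p) for k in sizes}
    rank_sum = np.zeros(p)

    for _ in range(config.n_runs):
        tr_idx, te_idx = [], []
        for cls_idx in idx_by_class:
            chosen = rng.permutation(cls_idx)[:n_bal]
            tr_idx.append(chosen[:n_tr])
            te_idx.append(chosen[n_tr:])
        tr = np.concatenate(tr_idx)
        te = np.concatenate(te_idx)
        Xtr, Xte = X_all[tr], X_all[te]
        ytr = (y_all[tr] == positive)
        mu = np.nanmean(Xtr, axis=0)
        sd = np.nanstd(Xtr, axis=0, ddof=0)
        sd[~(sd > 0)] = 1.0
        Ztr = (np.where(np.isnan(Xtr), mu, Xtr) - mu) / sd
        Zte = (np.where(np.isnan(Xte), mu, Xte) - mu) / sd
        order = rank_features(Ztr, ytr, C=config.C)
        rank_sum[order] += np.arange(1, p + 1)
        for k in sizes:
            feats = order[:k]
            svc = SVC(kernel=config.kernel, C=config.C)
            svc.fit(Ztr[:, feats], ytr)
            d_tr = svc.decision_function(Ztr[:, feats]).reshape(-1, 1)
            d_te = svc.decision_function(Zte[:, feats]).reshape(-1, 1)
            platt = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
            platt.fit(d_tr, ytr)
            pos_col = int(np.flatnonzero(platt.classes_ == True)[0])
            p_te = platt.predict_proba(d_te)[:, pos_col]
            prob_sum[k][te] += p_te
            prob_cnt[k][te] += 1
            sel_cnt[k][feats] += 1

    excluded = [traits.index[i] for i in range(n)
                if any(prob_cnt[k][i] == 0 for k in sizes)]
    if excluded:
        import warnings
        warnings.warn(f"{len(excluded)} sample(s) never held out; excluded "
                      f"from the averaged ROC", stacklevel=2)
    auc_by, acc_by, roc_by = {}, {}, {}
    avg = {}
    y_pos = (y_all == positive)
    for k in sizes:
        with np.errstate(invalid="ignore"):
            pbar = prob_sum[k] / prob_cnt[k]
        avg[k] = pbar
        ok = prob_cnt[k] > 0
        fpr, tpr, a = average_roc(pbar[ok], y_pos[ok])
        auc_by[k], roc_by[k] = a, (fpr, tpr)
        acc_by[k] = float(np.mean((pbar[ok] > 0.5) == y_pos[ok]))
    best = max(sizes, key=lambda k: (auc_by[k], acc_by[k], -k))
    return ModelSweepResult(
        sizes=sizes, auc=auc_by, accuracy=acc_by, roc=roc_by,
        avg_probability=pd.DataFrame(avg, index=traits.index),
        selection_frequency=pd.DataFrame(
            {k: sel_cnt[k] / config.n_runs for k in sizes}, index=traits.columns),
        mean_importance_rank=pd.Series(rank_sum / config.n_runs,
                                       index=traits.columns).sort_values(),
        best_size=best, positive_label=positive, n_runs=config.n_runs,
        excluded_samples=excluded)


def average_roc(probabilities: np.ndarray, is_positive: np.ndarray):
    """Single ROC/AUC over per-sample averaged probabilities (trapezoid)."""
    fpr, tpr, _ = roc_curve(is_positive, probabilities)
    return fpr, tpr, float(sk_auc(fpr, tpr))


@dataclass
class FittedModel:
    """A final biomarker model refit on a full cohort for external use."""

    features: list
    mean: np.ndarray
    sd: np.ndarray
    svc: SVC
    platt: LogisticRegression
    positive_label: object


def fit_final_model(traits: pd.DataFrame, labels: pd.Series, features,
                    positive=None, C: float = 1.0,
                    kernel: str = "linear") -> FittedModel:
    """Refit the selected-feature model on the whole (discovery) cohort."""
    labels = pd.Series(labels).reindex(traits.index)
    classes, positive = _canonical_classes(labels.to_numpy(), positive)
    X = traits[list(features)].to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=0)
    sd[~(sd > 0)] = 1.0
    Z = (np.where(np.isnan(X), mu, X) - mu) / sd
    y = (labels.to_numpy() == positive)
    svc = SVC(kernel=kernel, C=C)
    svc.fit(Z, y)
    d = svc.decision_function(Z).reshape(-1, 1)
    platt = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    platt.fit(d, y)
    return FittedModel(features=list(features), mean=mu, sd=sd, svc=svc,
                       platt=platt, positive_label=positive)


def apply_model(model: FittedModel, traits: pd.DataFrame,
                labels: pd.Series | None = None):
    """Class probabilities of a fitted model on an external cohort.

    Returns (probabilities, auc, accuracy); the last two are None without
    labels.
    """
    X = traits[model.features].to_numpy(dtype=float)
    Z = (np.where(np.isnan(X), model.mean, X) - model.mean) / model.sd
    d = model.svc.decision_function(Z).reshape(-1, 1)
    pos_col = int(np.flatnonzero(model.platt.classes_ == True)[0])
    probs = pd.Series(model.platt.predict_proba(d)[:, pos_col], index=traits.index)
    if labels is None:
        return probs, None, None
    y = (pd.Series(labels).reindex(traits.index).to_numpy() == model.positive_label)
    _, _, a = average_roc(probs.to_numpy(), y)
    acc = float(np.mean((probs.to_numpy() > 0.5) == y))
    return probs, a, acc
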