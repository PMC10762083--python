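"""Feature selection, per-family weak learners, AdaBoost fusion and the
continuous 0-100 cognitive score.

The fusion follows a printed AdaBoost variant exactly:

* every training sample starts at weight ``w = 1/N``;
* at each round the weak classifier with the smallest weighted error
  ``e`` (sum of weights of its misclassified samples) is selected and
  given the vote weight ``alpha = 0.5 * ln((2 - e) / e)``;
* sample weights then update to ``w / (2 (1 - e))`` for correctly
  classified samples and ``w / (2 e)`` for misclassified ones — the
  reading under which total weight is conserved (the correct mass
  ``1 - e`` maps to 1/2 and the wrong mass ``e`` maps to 1/2);
* rounds repeat without replacement until every classifier has a weight.

Note this vote-weight formula differs from classical AdaBoost's
``0.5 * ln((1 - e) / e)``: ``e = 0.5`` still earns a positive weight
(``0.5 * ln 3``).  The classical formula is available behind
``classic_alpha=True`` for comparison.

The continuous score maps the predicted class to a base score (HC 66.6,
MCI 33.3, dementia 0) and adds the regressed screening scales:
``score = base + 0.5 * (MoCAB + MMSE) / 30 * 33.3``, giving the ranges
66.6-100 / 33.3-66.6 / 0-33.3 for the three classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC, SVR

from .features import family_columns

__all__ = [
    "CLASS_BASE",
    "relieff",
    "WeakLearner",
    "train_weak",
    "adaboost_fuse",
    "EnsembleModel",
    "ScaleRegressors",
    "train_scale_regressors",
    "CognitiveScore",
    "cognitive_score",
    "true_cognitive_score",
    "alpha_from_error",
]

CLASS_BASE = {"HC": 66.6, "MCI": 33.3, "dementia": 0.0}
SCALE_MAX = 30.0
REGRESSION_SPAN = 33.3


# ---------------------------------------------------------------------------
# ReliefF


def relieff(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 10,
    n_keep: int | str | None = None,
) -> tuple:
    """Multi-class ReliefF feature weights and ranking.

    For every sample, the k nearest same-class neighbors (hits) decrease
    and the k nearest neighbors of each other class (misses, weighted by
    class prior over the complement) increase each feature's weight;
    feature differences are range-scaled.  All samples are used
    (``m = n``).  Returns ``(weights, ranked_indices)`` or, when
    ``n_keep`` is an integer, ``(weights, ranked_indices[:n_keep])``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, f = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("ReliefF needs at least two classes")
    smallest = counts.min()
    if k_neighbors >= smallest:
        raise ValueError(
            f"k_neighbors={k_neighbors} must be < smallest class size {smallest}"
        )
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    rng_span = X.max(axis=0) - X.min(axis=0)
    rng_span = np.where(rng_span > 0, rng_span, 1.0)
    Xs = X / rng_span

    d2 = ((Xs[:, None, :] - Xs[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)

    W = np.zeros(f)
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        hits = same[np.argsort(d2[i, same])[:k_neighbors]]
        W -= np.abs(Xs[hits] - Xs[i]).sum(axis=0) / (n * k_neighbors)
        for c in classes:
            if c == y[i]:
                continue
            other = np.flatnonzero(y == c)
            miss = other[np.argsort(d2[i, other])[:k_neighbors]]
            coef = priors[c] / (1.0 - priors[y[i]])
            W += coef * np.abs(Xs[miss] - Xs[i]).sum(axis=0) / (n * k_neighbors)
    ranked = np.argsort(-W, kind="stable")
    if isinstance(n_keep, int):
        return W, ranked[:n_keep]
    return W, ranked


# ---------------------------------------------------------------------------
# Weak learners


@dataclass
class WeakLearner:
    """One per-family margin classifier with its boosting bookkeeping."""

    family: str
    feature_names: list
    clf: SVC
    mean: np.ndarray
    std: np.ndarray
    error: float = float("nan")
    alpha: float = float("nan")

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.feature_names].to_numpy(dtype=float)
        X = (X - self.mean) / self.std
        return self.clf.predict(X)


def _zscore_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    return mean, std


def train_weak(
    df: pd.DataFrame,
    family: str,
    feature_names: list | None = None,
    *,
    k_neighbors: int = 8,
    n_keep: int = 10,
    C: float = 1.0,
) -> WeakLearner:
    """Train one family's weak classifier on (optionally selected) features.

    When ``feature_names`` is None, ReliefF ranks the family's columns on
    the training table and the top ``n_keep`` are used.  The classifier
    is an RBF-kernel SVM (one-vs-one voting for the three classes);
    feature z-scoring statistics come from this training table only.
    """
    y = df["meta_label"].to_numpy()
    if feature_names is None:
        cols = family_columns(df, family)
        X = df[cols].to_numpy(dtype=float)
        keep_var = X.std(axis=0) > 0
        cols = [c for c, k in zip(cols, keep_var) if k]
        X = df[cols].to_numpy(dtype=float)
        _, top = relieff(X, y, k_neighbors=k_neighbors,
                         n_keep=min(n_keep, len(cols)))
        feature_names = [cols[i] for i in top]
    X = df[feature_names].to_numpy(dtype=float)
    mean, std = _zscore_fit(X)
    clf = SVC(kernel="rbf", C=C, gamma="scale")
    clf.fit((X - mean) / std, y)
    return WeakLearner(family=family, feature_names=list(feature_names),
                       clf=clf, mean=mean, std=std)


# ---------------------------------------------------------------------------
# AdaBoost fusion


def alpha_from_error(e: float, classic: bool = False) -> float:
    """Vote weight for error rate e: ``0.5*ln((2-e)/e)`` (or the classical
    ``0.5*ln((1-e)/e)`` when ``classic`` is set)."""
    if not 0.0 < e < 1.0:
        raise ValueError("error rate must lie in (0, 1)")
    num = (1.0 - e) if classic else (2.0 - e)
    return 0.5 * math.log(num / e)


@dataclass
class EnsembleModel:
    """Fused strong classifier: ordered weak learners with vote weights."""

    learners: list                       # WeakLearner, selection order
    classes: tuple
    classic_alpha: bool = False
    history: list = field(default_factory=list)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        votes = np.zeros((len(df), len(self.classes)))
        cls_index = {c: i for i, c in enumerate(self.classes)}
        for wl in self.learners:
            pred = wl.predict(df)
            for r, p in enumerate(pred):
                votes[r, cls_index[p]] += wl.alpha
        return np.asarray([self.classes[i] for i in votes.argmax(axis=1)])

    @property
    def alphas(self) -> dict:
        return {wl.family: wl.alpha for wl in self.learners}


def _clip_error(e: float, n: int) -> float:
    lo = 1.0 / (2.0 * n)
    return min(max(e, lo), 1.0 - lo)


def adaboost_fuse(
    learners: list,
    df: pd.DataFrame,
    classic_alpha: bool = False,
) -> EnsembleModel:
    """Fuse trained weak learners by the printed AdaBoost procedure.

    Samples start at ``w = 1/N``; at each round the unassigned learner
    with the smallest weighted error is selected, weighted, and the
    sample weights renormalized (correct mass to 1/2, wrong mass to 1/2);
    total sample weight is conserved at every step.  A sample counts as
    correct iff the predicted class equals the true class.
    """
    if len(learners) < 2:
        raise ValueError("need at least two weak learners to fuse")
    y = df["meta_label"].to_numpy()
    n = len(df)
    w = np.full(n, 1.0 / n)
    preds = {wl.family: wl.predict(df) for wl in learners}
    remaining = list(learners)
    ordered, history = [], []
    while remaining:
        errors = []
        for wl in remaining:
            e = float(w[preds[wl.family] != y].sum())
            errors.append(_clip_error(e, n))
        best = int(np.argmin(errors))
        wl = remaining.pop(best)
        e = errors[best]
        wl.error = e
        wl.alpha = alpha_from_error(e, classic=classic_alpha)
        correct = preds[wl.family] == y
        w = np.where(correct, w / (2.0 * (1.0 - e)), w / (2.0 * e))
        # the division reading conserves total mass exactly when e is the
        # true weighted error; renormalize so the invariant also survives
        # error clipping (e.g. a perfectly separating learner)
        w /= w.sum()
        history.append({
            "family": wl.family, "error": e, "alpha": wl.alpha,
            "weight_sum": float(w.sum()),
        })
        ordered.append(wl)
    if not any(wl.alpha > 0 for wl in ordered):
        raise ValueError("all vote weights are zero; fusion is degenerate")
    classes = tuple(sorted(set(y)))
    return EnsembleModel(learners=ordered, classes=classes,
                         classic_alpha=classic_alpha, history=history)


# ---------------------------------------------------------------------------
# Scale-score regression


@dataclass
class ScaleRegressors:
    """Per-family support-vector regressors fused by error-weighted vote.

    For each 0-30 scale (MoCA-B, MMSE) one RBF-kernel SVR per family; the
    fusion weight derives from the same printed schedule with
    ``e`` = weighted mean absolute error normalized by the scale maximum,
    and a sample counted as "correct" when its absolute error is at most
    ``tol_points`` (default 3) on the 0-30 scale.  The fused prediction
    is the alpha-weighted mean of family predictions, clipped to [0, 30].
    """

    per_scale: dict                      # scale -> list of (family, SVR-like, alpha)
    feature_sets: dict                   # family -> (names, mean, std)
    tol_points: float = 3.0

    def predict(self, df: pd.DataFrame, scale: str) -> np.ndarray:
        entries = self.per_scale[scale]
        total_a = sum(a for _, _, a in entries)
        acc = np.zeros(len(df))
        for fam, reg, a in entries:
            names, mean, std = self.feature_sets[fam]
            X = (df[names].to_numpy(dtype=float) - mean) / std
            acc += a * reg.predict(X)
        return np.clip(acc / total_a, 0.0, SCALE_MAX)


def train_scale_regressors(
    df: pd.DataFrame,
    feature_sets: dict,
    tol_points: float = 3.0,
    classic_alpha: bool = False,
) -> ScaleRegressors:
    """Train and fuse per-family scale regressors on the training table.

    ``feature_sets`` maps family -> (feature_names, mean, std) — usually
    the selections of the classification weak learners, so both branches
    share one ReliefF pass.
    """
    per_scale: dict = {}
    for scale, col in (("moca_b", "meta_moca_b"), ("mmse", "meta_mmse")):
        y = df[col].to_numpy(dtype=float)
        n = len(df)
        w = np.full(n, 1.0 / n)
        fitted = []
        for fam, (names, mean, std) in feature_sets.items():
            X = (df[names].to_numpy(dtype=float) - mean) / std
            reg = SVR(kernel="rbf", C=10.0, gamma="scale")
            reg.fit(X, y)
            fitted.append((fam, reg, np.clip(reg.predict(X), 0, SCALE_MAX)))
        remaining = list(fitted)
        entries = []
        while remaining:
            errs = []
            for fam, reg, pred in remaining:
                e = float((w * np.minimum(np.abs(pred - y) / SCALE_MAX, 1.0)).sum())
                errs.append(_clip_error(e, n))
            best = int(np.argmin(errs))
            fam, reg, pred = remaining.pop(best)
            e = errs[best]
            a = alpha_from_error(e, classic=classic_alpha)
            correct = np.abs(pred - y) <= tol_points
            ec = _clip_error(float(w[~correct].sum()), n)
            w = np.where(correct, w / (2.0 * (1.0 - ec)), w / (2.0 * ec))
            entries.append((fam, reg, a))
        per_scale[scale] = entries
    return ScaleRegressors(per_scale=per_scale, feature_sets=feature_sets,
                           tol_points=tol_points)


# ---------------------------------------------------------------------------
# Continuous cognitive score


@dataclass
class CognitiveScore:
    predicted_class: str
    base: float
    regression_component: float
    total: float


def cognitive_score(pred_class: str, moca_pred: float, mmse_pred: float) -> CognitiveScore:
    """0-100 cognitive score: class base plus regressed scale component.

    ``total = base + 0.5 * (MoCAB + MMSE) / 30 * 33.3``; HC at full
    scores reaches 99.9, dementia at zero scores 0.
    """
    for name, v in (("moca", moca_pred), ("mmse", mmse_pred)):
        if not 0.0 <= v <= SCALE_MAX:
            raise ValueError(f"{name} score {v} outside [0, {SCALE_MAX:g}]")
    base = CLASS_BASE[pred_class]
    reg = 0.5 * (moca_pred + mmse_pred) / SCALE_MAX * REGRESSION_SPAN
    return CognitiveScore(
        predicted_class=pred_class, base=base,
        regression_component=reg, total=base + reg,
    )


def true_cognitive_score(label: str, moca_b: float, mmse: float) -> float:
    """Ground-truth score: the same formula on the clinical label and the
    administered scale scores."""
    return cognitive_score(label, moca_b, mmse).total
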