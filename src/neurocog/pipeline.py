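"""End-to-end orchestration: training, cross-validation, external
evaluation and group statistics.

The validation protocol holds out 10 recordings per class per round
(independent stratified random holdouts, re-drawn each of 15 rounds),
with no two test recordings from the same subject within a round.  Each
round retrains feature selection, the seven weak learners, the AdaBoost
fusion and the scale regressors on the training records only, then
scores the held-out records on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import ensemble as ens
from .features import FAMILIES, FeatureConfig, build_feature_table
from .io import CANONICAL_64, Cohort

__all__ = [
    "CVPlan",
    "EvaluationReport",
    "train_model",
    "predict_scores",
    "run_cv",
    "evaluate_external",
    "group_report",
]


@dataclass
class CVPlan:
    """Cross-validation protocol parameters.

    ``subject_exclusive=False`` reproduces the published protocol (the
    test set never contains two recordings of one subject, but a test
    subject's other session may remain in training, giving 474 training
    records for a 504-record cohort); ``True`` additionally removes the
    held-out subjects' remaining sessions from the training set.
    """

    n_rounds: int = 15
    held_out_per_class: int = 10
    subject_exclusive: bool = False


@dataclass
class EvaluationReport:
    """Pooled and per-round evaluation of the fused model."""

    classes: tuple
    confusions: list                    # per-round 3x3 arrays
    round_accuracies: list
    round_maes: list
    true_scores: np.ndarray
    pred_scores: np.ndarray
    labels_true: np.ndarray
    labels_pred: np.ndarray
    devices: np.ndarray
    train_sizes: list = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        """Pooled accuracy over all held-out predictions."""
        return float((self.labels_true == self.labels_pred).mean())

    @property
    def mae(self) -> float:
        """Pooled mean absolute error on the 0-100 score."""
        return float(np.abs(self.true_scores - self.pred_scores).mean())

    @property
    def mean_round_mae(self) -> float:
        """Mean over rounds of the per-round MAE."""
        return float(np.mean(self.round_maes))

    def pooled_confusion(self) -> np.ndarray:
        return np.sum(self.confusions, axis=0)

    def per_class_mae(self) -> dict:
        out = {}
        for c in self.classes:
            m = self.labels_true == c
            out[c] = float(np.abs(self.true_scores[m] - self.pred_scores[m]).mean())
        return out

    def per_device_mae(self) -> dict:
        out = {}
        for d in np.unique(self.devices):
            m = self.devices == d
            out[str(d)] = float(np.abs(self.true_scores[m] - self.pred_scores[m]).mean())
        return out

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "score_mae": self.mae,
            "mean_round_mae": self.mean_round_mae,
            "per_class_mae": self.per_class_mae(),
            "per_device_mae": self.per_device_mae(),
            "confusion": self.pooled_confusion().tolist(),
            "classes": list(self.classes),
            "round_accuracies": list(map(float, self.round_accuracies)),
        }


def _confusion(y_true, y_pred, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[idx[t], idx[p]] += 1
    return m


def train_model(df_train: pd.DataFrame, *, n_keep: int = 10,
                k_neighbors: int = 8, classic_alpha: bool = False):
    """Fit the full model on a training feature table.

    ReliefF selection and z-scoring statistics use the training table
    only.  Returns ``(EnsembleModel, ScaleRegressors)``.
    """
    learners = [
        ens.train_weak(df_train, fam, n_keep=n_keep, k_neighbors=k_neighbors)
        for fam in FAMILIES
    ]
    fused = ens.adaboost_fuse(learners, df_train, classic_alpha=classic_alpha)
    feature_sets = {
        wl.family: (wl.feature_names, wl.mean, wl.std) for wl in fused.learners
    }
    regs = ens.train_scale_regressors(df_train, feature_sets,
                                      classic_alpha=classic_alpha)
    return fused, regs


def predict_scores(fused, regs, df: pd.DataFrame):
    """Predicted class and 0-100 cognitive score for each row."""
    labels = fused.predict(df)
    moca = regs.predict(df, "moca_b")
    mmse = regs.predict(df, "mmse")
    totals = np.array([
        ens.cognitive_score(l, a, b).total for l, a, b in zip(labels, moca, mmse)
    ])
    return labels, totals


def _draw_holdout(df: pd.DataFrame, plan: CVPlan, rng) -> np.ndarray:
    """Row indices of one stratified subject-respecting holdout."""
    test_idx = []
    used_subjects: set = set()
    for c in sorted(df["meta_label"].unique()):
        rows = df.index[df["meta_label"] == c].to_numpy()
        rng.shuffle(rows)
        picked = 0
        for r in rows:
            s = df.loc[r, "meta_subject_id"]
            if s in used_subjects:
                continue
            used_subjects.add(s)
            test_idx.append(r)
            picked += 1
            if picked == plan.held_out_per_class:
                break
        if picked < plan.held_out_per_class:
            raise ValueError(
                f"class {c}: only {picked} distinct subjects available for "
                f"a {plan.held_out_per_class}-per-class holdout"
            )
    return np.asarray(test_idx)


def run_cv(df: pd.DataFrame, plan: CVPlan | None = None, seed: int = 0,
           *, n_keep: int = 10, k_neighbors: int = 8) -> EvaluationReport:
    """Repeated stratified holdout cross-validation on a feature table.

    ``df`` is a feature table from :func:`~neurocog.features.build_feature_table`
    (features are label-free per recording, so they are computed once and
    reused; selection, normalization and all model fitting happen per
    round on the training rows only).
    """
    plan = plan or CVPlan()
    rng = np.random.default_rng(seed)
    classes = tuple(sorted(df["meta_label"].unique()))
    for c in classes:
        n_subj = df.loc[df["meta_label"] == c, "meta_subject_id"].nunique()
        if n_subj <= plan.held_out_per_class:
            raise ValueError(
                f"class {c} has {n_subj} subjects; plan needs more than "
                f"{plan.held_out_per_class}"
            )
    confusions, accs, maes, sizes = [], [], [], []
    yt, yp, st, sp, dev = [], [], [], [], []
    for _ in range(plan.n_rounds):
        test_idx = _draw_holdout(df, plan, rng)
        test = df.loc[test_idx]
        train = df.drop(index=test_idx)
        if plan.subject_exclusive:
            train = train[~train["meta_subject_id"].isin(test["meta_subject_id"])]
        fused, regs = train_model(train, n_keep=n_keep, k_neighbors=k_neighbors)
        labels, totals = predict_scores(fused, regs, test)
        truth = test["meta_label"].to_numpy()
        true_totals = np.array([
            ens.true_cognitive_score(l, a, b)
            for l, a, b in zip(truth, test["meta_moca_b"], test["meta_mmse"])
        ])
        confusions.append(_confusion(truth, labels, classes))
        accs.append(float((labels == truth).mean()))
        maes.append(float(np.abs(totals - true_totals).mean()))
        sizes.append(len(train))
        yt.extend(truth); yp.extend(labels)
        st.extend(true_totals); sp.extend(totals)
        dev.extend(test["meta_device"].to_numpy())
    return EvaluationReport(
        classes=classes, confusions=confusions, round_accuracies=accs,
        round_maes=maes, true_scores=np.asarray(st), pred_scores=np.asarray(sp),
        labels_true=np.asarray(yt), labels_pred=np.asarray(yp),
        devices=np.asarray(dev), train_sizes=sizes,
    )


def evaluate_external(fused, regs, cohort: Cohort, cfg: FeatureConfig | None = None,
                      target_labels=CANONICAL_64, seed: int = 0,
                      microstate_model=None) -> EvaluationReport:
    """Score an external cohort (e.g. 19-channel, MMSE-only).

    Channels are expanded to the canonical montage by nearest-neighbor
    duplication before feature extraction; when the training run's
    ``microstate_model`` is supplied, external windows are labeled in the
    training centroid space instead of refitting the clustering.  Records
    without MMSE are skipped with a log entry.  When MoCA-B is
    unavailable the ground truth substitutes MMSE for both scale terms
    (``0.5*(MMSE+MMSE)``); the prediction side always uses both
    regressors.
    """
    from .io import expand_channels

    cfg = cfg or FeatureConfig()
    kept, skipped = [], []
    for r in cohort:
        if r.mmse is None:
            skipped.append(r.key())
            continue
        kept.append(expand_channels(r, target_labels))
    if not kept:
        raise ValueError("no external record carries an MMSE score")
    df = build_feature_table(Cohort(recordings=kept), cfg, seed=seed,
                             microstate_model=microstate_model)
    labels, totals = predict_scores(fused, regs, df)
    truth = df["meta_label"].to_numpy()
    true_totals = np.array([
        ens.true_cognitive_score(l, mo if pd.notna(mo) else m, m)
        for l, m, mo in zip(truth, df["meta_mmse"], df["meta_moca_b"])
    ])
    classes = tuple(sorted(set(truth)))
    rep = EvaluationReport(
        classes=classes,
        confusions=[_confusion(truth, labels, classes)],
        round_accuracies=[float((labels == truth).mean())],
        round_maes=[float(np.abs(totals - true_totals).mean())],
        true_scores=true_totals, pred_scores=totals,
        labels_true=truth, labels_pred=labels,
        devices=df["meta_device"].to_numpy(),
    )
    rep.skipped = skipped  # type: ignore[attr-defined]
    return rep


def group_report(df: pd.DataFrame, bonferroni: bool = True) -> pd.DataFrame:
    """Per-feature two-group statistics for every class pair.

    A Kolmogorov-Smirnov normality gate routes each feature to a
    two-sample t-test (both groups consistent with normal) or a
    Mann-Whitney U test; significance is flagged at p < 0.1 and p < 0.05,
    optionally Bonferroni-corrected within each feature family.
    """
    feats = [c for c in df.columns if not c.startswith("meta_")]
    classes = sorted(df["meta_label"].unique())
    rows = []
    for f in feats:
        fam = f.split("/", 1)[0]
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                a = df.loc[df["meta_label"] == classes[i], f].to_numpy(dtype=float)
                b = df.loc[df["meta_label"] == classes[j], f].to_numpy(dtype=float)
                a, b = a[np.isfinite(a)], b[np.isfinite(b)]
                if a.size < 3 or b.size < 3 or (a.std() == 0 and b.std() == 0):
                    continue
                normal = all(
                    stats.kstest(stats.zscore(x), "norm").pvalue > 0.05
                    for x in (a, b) if x.std() > 0
                )
                if normal:
                    stat, p = stats.ttest_ind(a, b, equal_var=False)
                    test = "t"
                else:
                    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                    test = "mannwhitney"
                rows.append({
                    "feature": f, "family": fam,
                    "group_a": classes[i], "group_b": classes[j],
                    "test": test, "stat": float(stat), "p": float(p),
                })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if bonferroni:
        out["p_adj"] = out["p"] * out.groupby("family")["p"].transform("size")
        out["p_adj"] = out["p_adj"].clip(upper=1.0)
    else:
        out["p_adj"] = out["p"]
    out["sig_0.1"] = out["p_adj"] < 0.1
    out["sig_0.05"] = out["p_adj"] < 0.05
    return out
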