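"""Resampling design and classifier assessment.

The evaluation protocol reserves a stratified quarter of the samples as an
untouched holdout for final panel validation, then repeatedly splits the
remaining development set 4/5 train : 1/5 test (50 repeats by default,
stratified by largest-remainder rounding). Every ranking, tuning step and
accuracy curve is computed per repeat on the training part only and
averaged across repeats; 95 % confidence half-widths are
1.96 * sd / sqrt(n_repeats).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import LabeledDataset
from .rankers import FeatureRanking, fit_predict_svm

__all__ = [
    "SplitPlan", "AccuracyCurve", "ClasswiseMetrics",
    "make_split_plan", "accuracy_curve", "classwise_metrics",
    "ci_halfwidth", "predictor_set_tiers", "evaluate_fixed_panel",
]


@dataclass
class SplitPlan:
    """Holdout indices plus repeated stratified train/test splits of the
    development set. All index arrays refer to rows of one dataset."""

    holdout: np.ndarray
    repeats: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    @property
    def development(self) -> np.ndarray:
        dev = np.concatenate([self.repeats[0][0], self.repeats[0][1]])
        return np.sort(dev)

    def validate(self, n_samples: int) -> None:
        hold = set(self.holdout.tolist())
        dev = set(range(n_samples)) - hold
        for tr, te in self.repeats:
            tr_s, te_s = set(tr.tolist()), set(te.tolist())
            assert not (tr_s & hold) and not (te_s & hold)
            assert not (tr_s & te_s)
            assert tr_s | te_s == dev


@dataclass
class AccuracyCurve:
    """Mean test accuracy (with 95 % CI half-width) as a function of the
    number of top-ranked features used."""

    sizes: list[int]
    means: list[float]
    ci_halfwidths: list[float]
    method: str
    per_repeat: np.ndarray | None = None  # sizes x repeats

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("sizes must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_features": self.sizes,
            "mean_accuracy": self.means,
            "ci_halfwidth": self.ci_halfwidths,
            "method": self.method,
        })


@dataclass
class ClasswiseMetrics:
    """Per-class precision/recall with supports, plus overall accuracy.

    A class never predicted has undefined precision; a class absent from
    the truth has undefined recall. Both are stored as NaN and flagged.
    """

    classes: list[int]
    precision: dict[int, float]
    recall: dict[int, float]
    support: dict[int, int]
    accuracy: float
    confusion: pd.DataFrame

    def undefined_precision(self) -> list[int]:
        return [c for c in self.classes if math.isnan(self.precision[c])]

    def undefined_recall(self) -> list[int]:
        return [c for c in self.classes if math.isnan(self.recall[c])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class_id": self.classes,
            "precision": [self.precision[c] for c in self.classes],
            "recall": [self.recall[c] for c in self.classes],
            "support": [self.support[c] for c in self.classes],
        })


def _largest_remainder(counts: np.ndarray, frac: float) -> np.ndarray:
    """Per-class allocation of round(sum(counts)*frac) slots, proportional
    within +/-1 by the largest-remainder rule (remainder ties broken
    towards the earlier class)."""
    quotas = counts * frac
    base = np.floor(quotas).astype(int)
    total = int(round(quotas.sum()))
    short = total - int(base.sum())
    if short > 0:
        remainders = quotas - base
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return base


def make_split_plan(labels: np.ndarray, holdout_frac: float = 0.25,
                    n_repeats: int = 50, train_frac: float = 0.8,
                    seed: int = 0) -> SplitPlan:
    """Stratified holdout + repeated stratified train/test subsampling.

    Every class contributes proportionately (largest-remainder rounding)
    to the holdout and to each repeat's training part. Deterministic given
    the seed; each repeat draws from its own seed substream.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2].tolist()
        raise ValueError(f"every class needs >= 2 samples; too small: {small}")
    root = np.random.SeedSequence(seed)
    ss_hold, ss_rep = root.spawn(2)
    rng = np.random.default_rng(ss_hold)

    hold_counts = _largest_remainder(counts.astype(float), holdout_frac)
    holdout_parts, dev_parts = [], []
    for c, h in zip(classes, hold_counts):
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx)
        holdout_parts.append(perm[:h])
        dev_parts.append(perm[h:])
        if len(perm) - h == 0:
            raise ValueError(f"class {c} vanished from the development set")
    holdout = np.sort(np.concatenate(holdout_parts))
    dev_by_class = dev_parts

    repeats = []
    rep_streams = ss_rep.spawn(n_repeats)
    dev_counts = np.array([len(d) for d in dev_by_class], dtype=float)
    train_counts = _largest_remainder(dev_counts, train_frac)
    for stream in rep_streams:
        r = np.random.default_rng(stream)
        train_parts, test_parts = [], []
        for dev_idx, t in zip(dev_by_class, train_counts):
            perm = r.permutation(dev_idx)
            train_parts.append(perm[:t])
            test_parts.append(perm[t:])
        repeats.append((np.sort(np.concatenate(train_parts)),
                        np.sort(np.concatenate(test_parts))))
    plan = SplitPlan(holdout=holdout, repeats=repeats, seed=seed)
    plan.validate(len(labels))
    return plan


def ci_halfwidth(values) -> float:
    """95 % confidence half-width of a mean over resamples:
    1.96 * sd(values) / sqrt(len(values)), sample sd (n-1 denominator)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    return float(1.96 * values.std(ddof=1) / math.sqrt(values.size))


def classwise_metrics(true_labels, predicted_labels,
                      classes: list[int] | None = None) -> ClasswiseMetrics:
    """Exact per-class precision and recall by direct counting.

    precision_i = #(correctly classified as i) / #(classified as i)
    recall_i    = #(correctly classified as i) / #(of class i)
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label vectors must have equal length")
    if classes is None:
        cls = np.unique(np.concatenate([y_true, y_pred])).tolist()
    else:
        cls = list(classes)
        unknown = set(np.concatenate([y_true, y_pred]).tolist()) - set(cls)
        if unknown:
            raise ValueError(f"unknown label id(s): {sorted(unknown)}")
    pos = {c: i for i, c in enumerate(cls)}
    conf = np.zeros((len(cls), len(cls)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        conf[pos[t], pos[p]] += 1
    diag = np.diag(conf)
    pred_tot = conf.sum(axis=0)
    true_tot = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_tot > 0, diag / pred_tot, np.nan)
        rec = np.where(true_tot > 0, diag / true_tot, np.nan)
    return ClasswiseMetrics(
        classes=cls,
        precision={c: float(prec[pos[c]]) for c in cls},
        recall={c: float(rec[pos[c]]) for c in cls},
        support={c: int(true_tot[pos[c]]) for c in cls},
        accuracy=float(diag.sum() / len(y_true)) if len(y_true) else float("nan"),
        confusion=pd.DataFrame(conf, index=cls, columns=cls),
    )


def accuracy_curve(rankings: list[FeatureRanking], sizes: list[int],
                   plan: SplitPlan, dataset: LabeledDataset,
                   cost: float = 1.0, method: str = "svm_rfe") -> AccuracyCurve:
    """Mean test accuracy over repeats as a function of panel size.

    For repeat r and size n: restrict the matrix to the top-n features of
    ranking r (derived from that repeat's training set only), fit the SVM
    on train r, score on test r. Sizes beyond the feature count are
    truncated with a warning.
    """
    if len(rankings) != len(plan.repeats):
        raise ValueError("need exactly one ranking per resampling repeat")
    p = len(rankings[0])
    sizes = sorted(set(sizes))
    if sizes[-1] > p:
        warnings.warn(f"sizes beyond {p} features truncated")
        sizes = sorted({min(s, p) for s in sizes})
    acc = np.zeros((len(sizes), len(rankings)))
    for r, (ranking, (tr, te)) in enumerate(zip(rankings, plan.repeats)):
        train = dataset.subset_samples(tr)
        test = dataset.subset_samples(te)
        for i, n in enumerate(sizes):
            top = ranking.top(n)
            fit = fit_predict_svm(train.subset_features(top), cost=cost)
            pred = fit.predict(test.subset_features(top))
            acc[i, r] = float(np.mean(pred == test.labels))
    return AccuracyCurve(
        sizes=sizes,
        means=[float(a.mean()) for a in acc],
        ci_halfwidths=[ci_halfwidth(a) for a in acc],
        method=method,
        per_repeat=acc,
    )


def predictor_set_tiers(ranking: FeatureRanking, n: int
                        ) -> tuple[list[int], list[int], list[int]]:
    """Top, second-best and third-best predictor sets: ranks 1..n, n+1..2n
    and 2n+1..3n of the importance ranking."""
    if 3 * n > len(ranking):
        raise ValueError(f"need a ranking of length >= {3 * n}, got {len(ranking)}")
    ids = ranking.feature_ids
    return ids[:n], ids[n:2 * n], ids[2 * n:3 * n]


def evaluate_fixed_panel(panel: list[int], dataset: LabeledDataset,
                         plan: SplitPlan, cost: float = 1.0,
                         class_subset: list[int] | None = None) -> ClasswiseMetrics:
    """Train the SVM on the development 3/4 restricted to a fixed feature
    panel and score it on the untouched holdout 1/4.

    Panel features missing from the matrix are reported and dropped.
    ``class_subset`` restricts both training and evaluation to the listed
    cancer types (for comparisons covering only some of the classes).
    """
    have = set(dataset.matrix.feature_index())
    effective = [f for f in panel if f in have]
    missing = [f for f in panel if f not in have]
    if missing:
        warnings.warn(f"{len(missing)} panel feature(s) absent from the matrix; dropped")
    if not effective:
        raise ValueError("no panel feature is present in the matrix")
    sub = dataset.subset_features(effective)
    dev_idx, hold_idx = plan.development, plan.holdout
    if class_subset is not None:
        keep = np.isin(dataset.labels, class_subset)
        dev_idx = dev_idx[keep[dev_idx]]
        hold_idx = hold_idx[keep[hold_idx]]
    train = sub.subset_samples(dev_idx)
    hold = sub.subset_samples(hold_idx)
    fit = fit_predict_svm(train, cost=cost)
    pred = fit.predict(hold)
    return classwise_metrics(hold.labels, pred)
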