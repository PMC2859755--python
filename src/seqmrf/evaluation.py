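"""Classification performance measures and experiment drivers.

The discrimination score of a test sequence is its foreground log posterior
odds; every metric here depends on scores only through their ranking, so any
strictly monotone transform leaves the results unchanged.

Reported measures follow the signal-sequence benchmarking convention:
false positive rate at 95% sensitivity, sensitivity at 99.9% specificity,
positive predictive value at 95% sensitivity, area under the ROC curve, and
area under the precision-recall curve with Davis-Goadrich interpolation
(intermediate true-positive counts stepped one at a time, false positives
interpolated linearly between achievable points).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .learning import Classifier, TrainingConfig, train
from .seqdata import LabeledDataset, stratified_holdout_split
from .structures import ModelStructure

__all__ = [
    "ScoredTestSet",
    "PerformanceReport",
    "auc_roc",
    "auc_pr",
    "thresholded_metrics",
    "evaluate_scores",
    "score_test_set",
    "run_holdout_experiment",
]


@dataclass
class ScoredTestSet:
    """Per-sequence discrimination scores with ground-truth labels."""

    scores: np.ndarray
    positive: np.ndarray  # True for foreground sequences

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.positive = np.asarray(self.positive, dtype=bool)
        if self.scores.shape != self.positive.shape:
            raise ValueError("scores and labels differ in shape")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @property
    def n_pos(self) -> int:
        return int(self.positive.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.positive).sum())

    def _require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError("curve metrics need at least one positive and one negative")


@dataclass
class PerformanceReport:
    """The five-measure summary of one scored test set."""

    fpr_at_sn: float
    sn_at_sp: float
    ppv_at_sn: float
    auc_roc: float
    auc_pr: float
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict:
        return {
            "fpr_at_sn": self.fpr_at_sn, "sn_at_sp": self.sn_at_sp,
            "ppv_at_sn": self.ppv_at_sn, "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr, "n_pos": self.n_pos, "n_neg": self.n_neg,
        }


def _curve_points(scored: ScoredTestSet) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (TP, FP) at every distinct threshold, ties grouped.

    Point ``j`` counts predictions with score >= the j-th largest distinct
    score; an implicit (0, 0) point precedes the list.
    """
    order = np.argsort(-scored.scores, kind="mergesort")
    s = scored.scores[order]
    pos = scored.positive[order]
    boundaries = np.flatnonzero(np.diff(s)) + 1
    ends = np.append(boundaries, len(s))
    tp_cum = np.cumsum(pos)
    fp_cum = np.cumsum(~pos)
    return tp_cum[ends - 1], fp_cum[ends - 1]


def auc_roc(scored: ScoredTestSet) -> float:
    """Area under the ROC curve, trapezoidal over grouped thresholds.

    Equals the Mann-Whitney pairwise statistic with ties counted one half.
    """
    scored._require_both_classes()
    tp, fp = _curve_points(scored)
    tpr = np.concatenate(([0.0], tp / scored.n_pos, [1.0]))
    fpr = np.concatenate(([0.0], fp / scored.n_neg, [1.0]))
    return float(np.trapezoid(tpr, fpr))


def auc_pr(scored: ScoredTestSet, interpolation: str = "davis-goadrich") -> float:
    """Area under the precision-recall curve.

    ``davis-goadrich`` (default) interpolates between achievable points by
    stepping intermediate true positives one at a time with false positives
    linear in TP, the correct nonlinear interpolation in PR space;
    ``trapezoid`` integrates the raw achievable points directly (available
    for sensitivity analysis).
    """
    scored._require_both_classes()
    tp, fp = _curve_points(scored)
    P = scored.n_pos
    tp = np.concatenate(([0], tp))
    fp = np.concatenate(([0], fp))
    if interpolation == "trapezoid":
        mask = tp > 0
        recall = tp[mask] / P
        prec = tp[mask] / (tp[mask] + fp[mask])
        if recall[0] > 0:
            recall = np.concatenate(([0.0], recall))
            prec = np.concatenate(([prec[0]], prec))
        return float(np.trapezoid(prec, recall))
    if interpolation != "davis-goadrich":
        raise ValueError(f"unknown interpolation {interpolation!r}")
    # Between achievable points, FP is linear in TP, so the interpolated
    # precision is p(t) = t / (t (1+s) + k) with s the FP/TP slope.  Each
    # segment integrates in closed form:
    #   integral p dr = [ (tb - ta) - k' ln((tb + k')/(ta + k')) ] / (P (1+s))
    # with k' = (fp_a - s * tp_a) / (1+s); the segment leaving (0, 0) has
    # constant precision, which extends the curve flat toward recall 0.
    area = 0.0
    for j in range(1, len(tp)):
        ta, tb = float(tp[j - 1]), float(tp[j])
        fa, fb = float(fp[j - 1]), float(fp[j])
        d_tp = tb - ta
        if d_tp == 0:
            continue
        s = (fb - fa) / d_tp
        k = (fa - s * ta) / (1.0 + s)
        if abs(k) < 1e-12:
            area += d_tp / (P * (1.0 + s))
        else:
            area += (d_tp - k * np.log((tb + k) / (ta + k))) / (P * (1.0 + s))
    return float(area)


def thresholded_metrics(scored: ScoredTestSet, sn_target: float = 0.95,
                        sp_target: float = 0.999) -> dict:
    """FPR and PPV at fixed sensitivity, and Sn at fixed specificity.

    The fixed-sensitivity threshold is the largest threshold with
    ``Sn >= sn_target`` (the most conservative one attaining the target); the
    fixed-specificity threshold is the smallest with ``Sp >= sp_target``.
    """
    scored._require_both_classes()
    if not (0 < sn_target <= 1) or not (0 < sp_target <= 1):
        raise ValueError("targets must be in (0, 1]")
    tp, fp = _curve_points(scored)
    P, Nn = scored.n_pos, scored.n_neg
    sn = tp / P
    sp = 1.0 - fp / Nn
    j_sn = int(np.argmax(sn >= sn_target))  # first index attaining the target
    fpr_at_sn = float(fp[j_sn] / Nn)
    ppv_at_sn = float(tp[j_sn] / (tp[j_sn] + fp[j_sn]))
    ok = np.flatnonzero(sp >= sp_target)
    sn_at_sp = float(sn[ok[-1]]) if len(ok) else 0.0
    return {"fpr_at_sn": fpr_at_sn, "ppv_at_sn": ppv_at_sn, "sn_at_sp": sn_at_sp}


def evaluate_scores(scored: ScoredTestSet, sn_target: float = 0.95,
                    sp_target: float = 0.999) -> PerformanceReport:
    t = thresholded_metrics(scored, sn_target, sp_target)
    return PerformanceReport(
        fpr_at_sn=t["fpr_at_sn"], sn_at_sp=t["sn_at_sp"], ppv_at_sn=t["ppv_at_sn"],
        auc_roc=auc_roc(scored), auc_pr=auc_pr(scored),
        n_pos=scored.n_pos, n_neg=scored.n_neg,
    )


def score_test_set(classifier: Classifier, test: LabeledDataset,
                   positive_class: int = 0) -> ScoredTestSet:
    return ScoredTestSet(scores=classifier.decision_scores(test),
                         positive=test.labels == positive_class)


# ----------------------------------------------------------------------
# Experiment drivers
# ----------------------------------------------------------------------

def run_holdout_experiment(
    fg: LabeledDataset, bg: LabeledDataset,
    classifiers: dict[str, tuple[ModelStructure | Sequence[ModelStructure], TrainingConfig]],
    fractions: Sequence[float] = (1.0,),
    repeats: int = 10,
    seed: int = 0,
    holdout_fraction: float = 0.1,
    metric_names: Sequence[str] = ("fpr_at_sn", "sn_at_sp", "ppv_at_sn", "auc_roc", "auc_pr"),
    keep_raw: bool = False,
) -> pd.DataFrame:
    """Repeated stratified-holdout comparison of several classifiers.

    Per repeat, one stratified split of foreground and background is drawn;
    for each training fraction, one sub-sampled training set is shared by all
    classifiers, which are then scored on the same held-out test set.
    Returns mean and standard error (sample SD / sqrt(repeats)) per
    (classifier, fraction, metric); with ``keep_raw`` a per-repeat column of
    raw values is included.  Deterministic given ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.generate_state(repeats * len(fractions) * 2).reshape(
        repeats, len(fractions), 2) % (2 ** 31)
    records: list[dict] = []
    for rep in range(repeats):
        for fi_, frac in enumerate(fractions):
            split_seed, train_seed = repeat_seeds[rep, fi_]
            # the same split per repeat: reuse the first fraction's split seed
            train_set, test_set = stratified_holdout_split(
                fg, bg, holdout_fraction=holdout_fraction,
                train_fraction=frac, seed=int(repeat_seeds[rep, 0, 0]))
            for name, (structure, config) in classifiers.items():
                cfg = TrainingConfig(**{**config.__dict__, "seed": int(train_seed)})
                clf = train(cfg, structure, train_set)
                report = evaluate_scores(score_test_set(clf, test_set))
                rec = {"classifier": name, "fraction": frac, "repeat": rep}
                rec.update({k: report.as_dict()[k] for k in metric_names})
                records.append(rec)
    raw = pd.DataFrame.from_records(records)
    long = raw.melt(id_vars=["classifier", "fraction", "repeat"],
                    value_vars=list(metric_names),
                    var_name="metric", value_name="value")
    out = (long.groupby(["classifier", "fraction", "metric"])  # type: ignore[call-overload]
           .agg(mean=("value", "mean"),
                se=("value", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0))
           .reset_index())
    if keep_raw:
        out.attrs["raw"] = raw
    return out


def run_fixed_split_experiment(
    train_set: LabeledDataset, test_set: LabeledDataset,
    classifiers: dict[str, tuple[ModelStructure | Sequence[ModelStructure], TrainingConfig]],
    metric_names: Sequence[str] = ("fpr_at_sn", "auc_roc", "ppv_at_sn", "auc_pr"),
) -> pd.DataFrame:
    """Pre-partitioned train/test comparison of a classifier grid.

    The protocol of benchmark datasets that ship a fixed split: every
    classifier is trained on the same training set and scored on the same
    test set; one row per (classifier, metric).
    """
    records = []
    for name, (structure, config) in classifiers.items():
        clf = train(config, structure, train_set)
        report = evaluate_scores(score_test_set(clf, test_set))
        for metric in metric_names:
            records.append({"classifier": name, "metric": metric,
                            "value": report.as_dict()[metric]})
    return pd.DataFrame.from_records(records)
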