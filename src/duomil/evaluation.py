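"""Slide-level aggregation, ROC/PR analysis, thresholds, CV folds, metrics.

A slide's score is the arithmetic mean of its patch-level head
probabilities; each class is then decided independently by a strict
threshold on its mean (defaults 0.905 for the normal head, 0.096 for the
coeliac head). Decision thresholds are chosen at the sensitivity =
specificity balance point. Cross-validation folds are assigned at the case
level (every scan of a patient sample shares a fold) with approximate
class stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from .manifest import SlideRecord


@dataclass(frozen=True)
class SlideScore:
    """Mean patch probability per head for one slide."""

    slide_id: str
    mean_normal: float
    mean_coeliac: float
    n_tiles: int


@dataclass(frozen=True)
class ThresholdPair:
    """Decision thresholds applied to the two head means (strict >)."""

    t_normal: float = 0.905
    t_coeliac: float = 0.096

    def __post_init__(self) -> None:
        for t in (self.t_normal, self.t_coeliac):
            if not (0.0 < t < 1.0):
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class SlideDecision:
    slide_id: str
    normal_positive: bool
    coeliac_positive: bool

    @property
    def discordant(self) -> bool:
        """True when the two independent head decisions disagree in kind."""
        return self.normal_positive == self.coeliac_positive


def slide_score(per_tile_predictions: np.ndarray, slide_id: str = "") -> SlideScore:
    """Arithmetic mean of the per-tile (normal, coeliac) probabilities."""
    preds = np.asarray(per_tile_predictions, dtype=np.float64)
    if preds.ndim != 2 or preds.shape[1] != 2 or preds.shape[0] == 0:
        raise ValueError("predictions must be a non-empty n x 2 array")
    means = preds.mean(axis=0)
    return SlideScore(slide_id=slide_id, mean_normal=float(means[0]),
                      mean_coeliac=float(means[1]), n_tiles=preds.shape[0])


def classify_slide(score: SlideScore,
                   thresholds: ThresholdPair = ThresholdPair()) -> SlideDecision:
    """Independent strict-threshold decision per head.

    Both-positive and neither-positive outcomes are representable and
    flagged via :attr:`SlideDecision.discordant`, mirroring the fact that
    the two heads are trained and thresholded separately.
    """
    return SlideDecision(
        slide_id=score.slide_id,
        normal_positive=score.mean_normal > thresholds.t_normal,
        coeliac_positive=score.mean_coeliac > thresholds.t_coeliac,
    )


@dataclass(frozen=True)
class RocPrResult:
    fpr: np.ndarray
    tpr: np.ndarray
    roc_auc: float
    precision: np.ndarray
    recall: np.ndarray
    pr_auc: float


def roc_and_pr(scores: np.ndarray, labels: np.ndarray) -> RocPrResult:
    """ROC and PR curves over all score thresholds, with trapezoidal AUCs."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    roc_auc = float(_skm.auc(fpr, tpr))
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    # precision_recall_curve returns recall descending; reverse (preserving
    # curve order through tied recalls) and integrate trapezoidally
    pr_auc = float(np.trapezoid(precision[::-1], recall[::-1]))
    return RocPrResult(fpr=fpr, tpr=tpr, roc_auc=roc_auc,
                       precision=precision, recall=recall, pr_auc=pr_auc)


def _threshold_candidates(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _balance_gap(scores: np.ndarray, labels: np.ndarray,
                 candidates: np.ndarray) -> np.ndarray:
    pos = labels.astype(bool)
    n_pos, n_neg = pos.sum(), (~pos).sum()
    pred = scores[None, :] > candidates[:, None]
    tpr = (pred & pos).sum(axis=1) / n_pos
    tnr = (~pred & ~pos).sum(axis=1) / n_neg
    return np.abs(tpr - tnr)


def select_threshold(scores: np.ndarray, labels: np.ndarray,
                     folds: np.ndarray | None = None,
                     rule: str = "balance") -> float:
    """Decision threshold at the sensitivity = specificity balance point.

    Candidates are midpoints between consecutive distinct scores plus the
    two infinite endpoints. With ``folds`` given, the objective
    |TPR - TNR| is averaged over folds (each fold evaluated on its own
    scores); ties resolve to the lowest candidate.

    ``rule="tpr-fpr"`` instead minimises |TPR - FPR| — the literal reading
    of "minimise the difference between the true- and false-positive
    rates". That objective is optimised at a chance-level operating point
    (TPR = FPR holds on the diagonal of ROC space), so the balance rule is
    the default; the literal variant is retained behind this switch.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if np.unique(scores).size == 1:
        raise ValueError("degenerate scores: all values identical")
    candidates = _threshold_candidates(scores)

    def gap(s: np.ndarray, y: np.ndarray) -> np.ndarray:
        if rule == "balance":
            return _balance_gap(s, y, candidates)
        if rule == "tpr-fpr":
            pos = y.astype(bool)
            pred = s[None, :] > candidates[:, None]
            tpr = (pred & pos).sum(axis=1) / pos.sum()
            fpr = (pred & ~pos).sum(axis=1) / (~pos).sum()
            return np.abs(tpr - fpr)
        raise ValueError(f"unknown rule {rule!r}")

    if folds is None:
        objective = gap(scores, labels)
    else:
        folds = np.asarray(folds)
        parts = []
        for f in np.unique(folds):
            sel = folds == f
            if labels[sel].all() or not labels[sel].any():
                continue  # a one-class fold cannot contribute both rates
            parts.append(gap(scores[sel], labels[sel]))
        if not parts:
            raise ValueError("no fold contains both classes")
        objective = np.mean(parts, axis=0)
    best = int(np.argmin(objective))  # first minimiser = lowest candidate
    return float(candidates[best])


def make_folds(records: list[SlideRecord], k: int = 5,
               rng: np.random.Generator | int | None = None) -> dict[str, int]:
    """Case-level stratified fold assignment, ``case_id -> fold`` in 1..k.

    All slides of a case share a fold. Cases are stratified by class
    (a case counts as coeliac if any of its slides is), shuffled within
    each class, and dealt round-robin with a running position so per-fold
    class counts stay within one case of perfect stratification and fold
    sizes stay balanced.
    """
    rng = np.random.default_rng(rng)
    case_label: dict[str, str] = {}
    for r in records:
        prev = case_label.get(r.case_id)
        if prev is None or r.label == "coeliac":
            case_label[r.case_id] = r.label if prev is None or r.is_positive else prev
    cases = sorted(case_label)
    if len(cases) < k:
        raise ValueError("fewer cases than folds")
    labels_present = set(case_label.values())
    if labels_present != {"normal", "coeliac"}:
        raise ValueError("both classes must be present")
    assignment: dict[str, int] = {}
    position = int(rng.integers(0, k))
    for cls in ("normal", "coeliac"):
        stratum = [c for c in cases if case_label[c] == cls]
        rng.shuffle(stratum)
        for case in stratum:
            assignment[case] = position % k + 1
            position += 1
    return assignment


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float


def compute_metrics(predicted_positive: np.ndarray,
                    actual_positive: np.ndarray) -> ClassMetrics:
    """Confusion counts and accuracy / precision / recall for one class.

    Ratios with a zero denominator are reported as NaN with a warning,
    never silently as 0.
    """
    pred = np.asarray(predicted_positive, dtype=bool)
    actual = np.asarray(actual_positive, dtype=bool)
    if pred.shape != actual.shape or pred.size == 0:
        raise ValueError("need at least one slide with matching shapes")
    tp = int(np.sum(pred & actual))
    fp = int(np.sum(pred & ~actual))
    tn = int(np.sum(~pred & ~actual))
    fn = int(np.sum(~pred & actual))
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    if tp + fp == 0:
        warnings.warn("no positive predictions: precision undefined")
        precision = float("nan")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive instances: recall undefined")
        recall = float("nan")
    else:
        recall = tp / (tp + fn)
    return ClassMetrics(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy,
                        precision=precision, recall=recall)
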