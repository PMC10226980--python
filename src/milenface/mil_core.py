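"""The multiple-instance-learning mathematics.

Instance scores are unbounded reals (logits) throughout; a sigmoid is
applied only inside the losses. Bag scores come from MIL pooling of the
instance scores: ``max``, ``mean``, or the default top-k mean (k=3), a
robustified max. Model selection uses the bag-level ROC AUC of max-pooled
scores; the operating threshold is the ROC point maximizing the geometric
mean of sensitivity and specificity on validation bags.

Because instances inherit their bag's label, positive bags contain
mislabeled (actually lesion-free) instances while negative bags do not —
asymmetric label noise. Instance-level accuracy is therefore expected to be
low for a well-behaved model, and the losses weight healthy instances more
heavily (factor 2 by default) to suppress false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ScoreSet",
    "ThresholdResult",
    "EvalReport",
    "mil_pool_topk",
    "mil_pool_max",
    "mil_pool_mean",
    "pool",
    "instance_loss",
    "instance_loss_grad",
    "prepool_loss",
    "auc_mil",
    "select_threshold",
    "evaluate",
]


@dataclass
class ScoreSet:
    """Instance scores (logit scale) of one bag plus its pooled bag score."""

    instance_scores: np.ndarray
    bag_label: int | None = None
    bag_score: float | None = None
    decision: int | None = None
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.instance_scores = np.asarray(self.instance_scores, dtype=np.float64)

    def pooled(self, method: str = "topk", k: int = 3) -> float:
        return pool(self.instance_scores, method, k)


@dataclass(frozen=True)
class ThresholdResult:
    """Operating threshold with the ROC statistics that selected it."""

    threshold: float
    tpr: float
    fpr: float
    gmean: float


@dataclass
class EvalReport:
    """Bag- and instance-level evaluation metrics.

    ``corrected`` metrics do not penalize a negative decision on a diabetic
    bag that shows no visible disease signs (severity ``no_signs``): such
    bags, when predicted negative, are re-assigned from the false-negative
    pool to the true negatives.
    """

    roc_auc: float = np.nan
    auc_mil: float = np.nan
    f1: float = np.nan
    accuracy: float = np.nan
    corrected_accuracy: float = np.nan
    corrected_precision: float = np.nan
    instance_accuracy: float = np.nan
    instance_precision: float = np.nan
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def to_dict(self) -> dict:
        return {
            "roc_auc": self.roc_auc,
            "auc_mil": self.auc_mil,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "corrected_accuracy": self.corrected_accuracy,
            "corrected_precision": self.corrected_precision,
            "instance_accuracy": self.instance_accuracy,
            "instance_precision": self.instance_precision,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def _check_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores must be a non-empty 1-D array")
    return scores


def mil_pool_topk(scores, k: int = 3) -> float:
    """Arithmetic mean of the k largest scores (duplicates both counted)."""
    scores = _check_scores(scores)
    if not 1 <= k <= scores.size:
        raise ValueError(f"k={k} out of range for {scores.size} scores")
    top = np.partition(scores, scores.size - k)[scores.size - k :]
    return float(top.mean())


def mil_pool_max(scores) -> float:
    return float(_check_scores(scores).max())


def mil_pool_mean(scores) -> float:
    return float(_check_scores(scores).mean())


def pool(scores, method: str = "topk", k: int = 3) -> float:
    if method == "topk":
        return mil_pool_topk(scores, min(k, len(np.atleast_1d(scores))))
    if method == "max":
        return mil_pool_max(scores)
    if method == "mean":
        return mil_pool_mean(scores)
    raise ValueError(f"unknown pooling {method!r}")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return labels.astype(np.float64)


def _bce_from_logits(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Elementwise, numerically stable BCE(sigmoid(logit), label)."""
    return np.logaddexp(0.0, logits) - labels * logits


def instance_loss(instance_logits, bag_labels, healthy_weight: float = 2.0) -> float:
    """Weighted mean binary cross entropy of instances vs inherited labels.

    Healthy (label 0) instances are up-weighted by ``healthy_weight``
    (default 2): positive bags carry label noise, negative bags do not, so
    trusting healthy instances more lowers the false-positive rate.
    """
    logits = np.asarray(instance_logits, dtype=np.float64)
    labels = _check_labels(bag_labels)
    if logits.shape != labels.shape:
        raise ValueError("logits and labels must be aligned")
    if healthy_weight <= 0:
        raise ValueError("healthy_weight must be positive")
    weights = np.where(labels == 0, healthy_weight, 1.0)
    return float(np.mean(weights * _bce_from_logits(logits, labels)))


def instance_loss_grad(
    instance_logits: np.ndarray, bag_labels: np.ndarray, healthy_weight: float = 2.0
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. the logits (training helper)."""
    logits = np.asarray(instance_logits, dtype=np.float64)
    labels = _check_labels(bag_labels)
    weights = np.where(labels == 0, healthy_weight, 1.0)
    loss = float(np.mean(weights * _bce_from_logits(logits, labels)))
    sig = 1.0 / (1.0 + np.exp(-logits))
    grad = weights * (sig - labels) / logits.size
    return loss, grad


def prepool_loss(
    instance_logits_per_bag, bag_labels, pooling: str = "topk", k: int = 3
) -> float:
    """BCE applied to the pooled bag logit against the bag label.

    The comparison mode in which MIL pooling happens before the loss,
    removing instance label noise but also the data-size benefit of
    instancing. Not the default training loss.
    """
    labels = _check_labels(bag_labels)
    if len(instance_logits_per_bag) != labels.size:
        raise ValueError("one logit list per bag label required")
    pooled = np.array(
        [pool(np.asarray(s, dtype=np.float64), pooling, k) for s in instance_logits_per_bag]
    )
    return float(np.mean(_bce_from_logits(pooled, labels)))


# ---------------------------------------------------------------------------
# bag AUC and thresholding
# ---------------------------------------------------------------------------

def auc_mil(bag_labels, instance_scores_per_bag, pooling: str = "max", k: int = 3) -> float:
    """Bag-level ROC AUC of pooled instance scores (early-stopping metric).

    Default pooling is ``max``; ties receive the Mann-Whitney half credit.
    """
    labels = _check_labels(bag_labels)
    if len(instance_scores_per_bag) != labels.size:
        raise ValueError("one score list per bag label required")
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to compute an AUC")
    pooled = [pool(np.asarray(s, dtype=np.float64), pooling, k) for s in instance_scores_per_bag]
    return float(roc_auc_score(labels, pooled))


def select_threshold(bag_labels, bag_scores) -> ThresholdResult:
    """Threshold maximizing sqrt(TPR * (1 - FPR)) over all ROC operating points.

    Candidates are the midpoints between consecutive distinct sorted scores
    plus sentinels beyond both extremes; ties in the geometric mean break
    toward the higher threshold (fewer positive decisions). Decisions are
    ``score > threshold``.
    """
    labels = _check_labels(bag_labels)
    scores = np.asarray(bag_scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must be aligned")
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to select a threshold")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        ([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0])
    )
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    decided = scores[None, :] > candidates[:, None]
    tpr = decided[:, pos].sum(axis=1) / n_pos
    fpr = decided[:, ~pos].sum(axis=1) / n_neg
    gmean = np.sqrt(tpr * (1.0 - fpr))
    best = np.flatnonzero(gmean == gmean.max()).max()
    return ThresholdResult(
        threshold=float(candidates[best]),
        tpr=float(tpr[best]),
        fpr=float(fpr[best]),
        gmean=float(gmean[best]),
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(
    bag_labels,
    severities,
    decisions,
    bag_scores=None,
    instance_scores_per_bag=None,
    instance_labels=None,
    instance_decisions=None,
    early_stop_pooling: str = "max",
    pool_k: int = 3,
) -> EvalReport:
    """Assemble the evaluation report for a set of bag decisions.

    Confusion counts (tp/fp/tn/fn) are the uncorrected ones; corrected
    metrics re-assign ``no_signs`` bags predicted negative out of the
    false-negative pool before computing accuracy and precision.
    """
    labels = _check_labels(bag_labels).astype(int)
    decisions = _check_labels(decisions).astype(int)
    severities = list(severities)
    if not (len(labels) == len(decisions) == len(severities)):
        raise ValueError("labels, severities and decisions must be aligned")
    sev = np.array([s or "unknown" for s in severities])

    tp = int(np.sum((labels == 1) & (decisions == 1)))
    fp = int(np.sum((labels == 0) & (decisions == 1)))
    tn = int(np.sum((labels == 0) & (decisions == 0)))
    fn = int(np.sum((labels == 1) & (decisions == 0)))
    n = len(labels)
    excused = int(np.sum((labels == 1) & (decisions == 0) & (sev == "no_signs")))

    report = EvalReport(tp=tp, fp=fp, tn=tn, fn=fn)
    report.accuracy = (tp + tn) / n
    report.corrected_accuracy = (tp + tn + excused) / n
    denom = tp + fp
    report.corrected_precision = tp / denom if denom else np.nan
    denom = 2 * tp + fp + fn
    report.f1 = 2 * tp / denom if denom else np.nan

    if bag_scores is not None and len(set(labels.tolist())) == 2:
        report.roc_auc = float(roc_auc_score(labels, np.asarray(bag_scores, dtype=np.float64)))
    if instance_scores_per_bag is not None and len(set(labels.tolist())) == 2:
        report.auc_mil = auc_mil(labels, instance_scores_per_bag, early_stop_pooling, pool_k)
    if instance_labels is not None and instance_decisions is not None:
        il = _check_labels(instance_labels).astype(int)
        idec = _check_labels(instance_decisions).astype(int)
        if il.shape != idec.shape:
            raise ValueError("instance labels and decisions must be aligned")
        report.instance_accuracy = float(np.mean(il == idec))
        pred_pos = int(np.sum(idec == 1))
        report.instance_precision = (
            float(np.sum((il == 1) & (idec == 1)) / pred_pos) if pred_pos else np.nan
        )
    return report
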