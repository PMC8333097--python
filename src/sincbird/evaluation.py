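"""File-level classification and the multi-metric evaluation suite.

A file (one labeled call) is classified by tiling it into frames, taking
the exponentiated LogSoftmax outputs, averaging these posterior vectors
over frames (probability space, as "average posterior" dictates; a
log-space option exists for comparison) and voting for the argmax, ties
broken toward the lowest class index.  Metrics: accuracy, support-weighted
one-vs-rest ROC AUC computed from the mean posteriors, weighted
precision/recall/F1, top-3/top-5 accuracy, and a row-proportion confusion
matrix.  The overlap-credit analysis quantifies how many wrong predictions
land on a species that acoustically overlaps the tagged event.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from .labels import ListItem
from .network import FrameClassifier
from .training import AudioCache, tile_frames

__all__ = ["EvalReport", "OverlapCredit", "classify_file", "evaluate_items",
           "compute_metrics", "confusion_proportions", "overlap_credit"]


def classify_file(model: FrameClassifier, item: ListItem, cache: AudioCache,
                  shift: int | None = None,
                  log_space: bool = False) -> tuple[int, np.ndarray]:
    """Predict one item's class by frame-posterior voting.

    Returns (predicted class, mean posterior vector).  The evaluation
    stride defaults to the configured window shift.
    """
    cfg = model.cfg
    frames = tile_frames(item, cfg.frame_samples,
                         shift if shift is not None else cfg.shift_samples,
                         cfg.fs, cache)
    if frames.shape[0] == 0:
        raise ValueError(f"{item.path}: zero frames")
    logp = model.predict_log_proba(frames)
    if log_space:
        mean_post = np.exp(logp.mean(axis=0))
        mean_post /= mean_post.sum()
    else:
        mean_post = np.exp(logp).mean(axis=0)
    return int(np.argmax(mean_post)), mean_post


def evaluate_items(model: FrameClassifier, items: list[ListItem],
                   cache: AudioCache) -> "EvalReport":
    """Classify every test item and assemble the full report."""
    preds, posts = [], []
    for item in items:
        p, post = classify_file(model, item, cache)
        preds.append(p)
        posts.append(post)
    y_true = np.array([it.class_index for it in items])
    return compute_metrics(y_true, np.array(preds), np.vstack(posts),
                           n_classes=model.cfg.n_classes)


@dataclass
class EvalReport:
    y_true: np.ndarray
    y_pred: np.ndarray
    mean_posteriors: np.ndarray          # (n_files, n_classes)
    metrics: dict[str, float]
    confusion: np.ndarray                # row-proportion matrix
    observed_classes: np.ndarray         # bool per class: present in truth

    def to_json(self, path: str | Path) -> None:
        payload = {
            "metrics": self.metrics,
            "y_true": self.y_true.tolist(),
            "y_pred": self.y_pred.tolist(),
            "mean_posteriors": np.round(self.mean_posteriors, 6).tolist(),
            "confusion": np.round(self.confusion, 6).tolist(),
            "observed_classes": self.observed_classes.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def top_k_accuracy(y_true: np.ndarray, posteriors: np.ndarray, k: int) -> float:
    """Fraction of files whose true class is among the k largest posterior
    entries (stable sort; ties resolved toward lower class indices)."""
    order = np.argsort(-posteriors, axis=1, kind="stable")
    hits = (order[:, :k] == y_true[:, None]).any(axis=1)
    return float(hits.mean())


def _weighted_ovr_auc(y_true: np.ndarray, posteriors: np.ndarray) -> float:
    """One-vs-rest AUC per class present in the truth, weighted by support.

    Classes absent from the test truth are excluded (with a warning), as
    their one-vs-rest problem has no positive examples."""
    classes, counts = np.unique(y_true, return_counts=True)
    n_classes = posteriors.shape[1]
    absent = sorted(set(range(n_classes)) - set(classes.tolist()))
    if absent:
        warnings.warn(f"classes {absent} absent from test truth; "
                      "excluded from AUC weighting")
    aucs, weights = [], []
    for c, cnt in zip(classes, counts):
        pos = y_true == c
        if pos.all():
            continue  # no negatives either -> AUC undefined
        aucs.append(roc_auc_score(pos, posteriors[:, c]))
        weights.append(cnt)
    if not aucs:
        return float("nan")
    return float(np.average(aucs, weights=weights))


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    mean_posteriors: np.ndarray,
                    n_classes: int | None = None) -> EvalReport:
    """Assemble the metric suite from truths, predictions and posteriors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    posts = np.asarray(mean_posteriors, dtype=float)
    if len(y_true) == 0:
        raise ValueError("need at least one test file")
    if n_classes is None:
        n_classes = posts.shape[1]

    accuracy = float((y_true == y_pred).mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division handled explicitly
        precision, recall, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0)
    confusion, observed = confusion_proportions(y_true, y_pred, n_classes)
    metrics = {
        "accuracy": accuracy,
        "roc_auc": _weighted_ovr_auc(y_true, posts),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "top3": top_k_accuracy(y_true, posts, 3),
        "top5": top_k_accuracy(y_true, posts, 5),
    }
    return EvalReport(y_true=y_true, y_pred=y_pred, mean_posteriors=posts,
                      metrics=metrics, confusion=confusion,
                      observed_classes=observed)


def confusion_proportions(y_true: np.ndarray, y_pred: np.ndarray,
                          n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-proportion confusion matrix.

    Row r holds the distribution of predictions among files whose true
    class is r; rows of classes never observed in the truth are all zero
    and flagged False in the returned mask.
    """
    counts = np.zeros((n_classes, n_classes))
    np.add.at(counts, (np.asarray(y_true), np.asarray(y_pred)), 1.0)
    row_sums = counts.sum(axis=1)
    observed = row_sums > 0
    matrix = np.zeros_like(counts)
    matrix[observed] = counts[observed] / row_sums[observed, None]
    return matrix, observed


@dataclass
class OverlapCredit:
    """Accuracy with credit for predictions landing on overlapping species."""

    strict_accuracy: float
    credited_accuracy: float
    # among wrong predictions, share that named an overlapping species
    errors_on_overlap_fraction: float
    # among predictions hitting the tag or an overlapping species,
    # the (tagged, overlap) shares
    tagged_share: float
    overlap_share: float


def overlap_credit(true_tags: list[str], pred_tags: list[str],
                   overlap_sets: list[set[str]]) -> OverlapCredit:
    """Re-score predictions giving credit for overlapping species.

    ``overlap_sets[i]`` is the set of other-species tags whose events
    intersect test event i's interval.  A prediction is credited if it
    matches the event's own tag OR any overlapping tag, so the credited
    accuracy can only exceed the strict one.
    """
    n = len(true_tags)
    if not (len(pred_tags) == len(overlap_sets) == n):
        raise ValueError("inputs must have equal length")
    strict = credited = on_overlap = errors = hits_any = hits_tagged = 0
    for t, p, ov in zip(true_tags, pred_tags, overlap_sets):
        correct = p == t
        in_overlap = p in ov
        strict += correct
        credited += correct or in_overlap
        if not correct:
            errors += 1
            on_overlap += in_overlap
        if correct or in_overlap:
            hits_any += 1
            hits_tagged += correct
    return OverlapCredit(
        strict_accuracy=strict / n,
        credited_accuracy=credited / n,
        errors_on_overlap_fraction=on_overlap / errors if errors else 0.0,
        tagged_share=hits_tagged / hits_any if hits_any else 0.0,
        overlap_share=(hits_any - hits_tagged) / hits_any if hits_any else 0.0,
    )
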