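"""Evaluation metrics and Grad-CAM saliency maps.

Metrics are the standard toolkit for multi-class radiograph classifiers:
multi-class accuracy, one-vs-rest AUC per class (midrank tie handling:
``AUC = P(score_pos > score_neg) + 0.5 P(tie)``) with an unweighted mean
over the classes for which AUC is defined, row-proportion confusion
matrices, and accuracy within groups (sites, age bins).

Grad-CAM weights the final convolutional feature map by the spatially
averaged gradient of the target-class logit, rectifies, bilinearly
upsamples to the input grid, and max-normalizes to [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from skimage import transform as sktransform

from .labels import ClassLabel, CLASS_NAMES, N_CLASSES
from .model import ReaderNet

__all__ = [
    "EvalReport",
    "multiclass_accuracy",
    "auc_ovr",
    "confusion_row_proportions",
    "grouped_accuracy",
    "age_groups",
    "gradcam",
    "evaluate_predictions",
]


def multiclass_accuracy(pred_labels: Sequence[int], true_labels: Sequence[int]) -> float:
    """Fraction of exact label matches."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("prediction and truth vectors must have equal nonzero length")
    return float(np.mean(pred == true))


def auc_ovr(
    prob_matrix: np.ndarray, true_labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """One-vs-rest AUC per class and the unweighted mean over defined classes.

    Per-class AUC is the Mann-Whitney statistic of that class's probability
    column: the probability a random positive outscores a random negative,
    ties counted half.  Classes without both a positive and a negative are
    reported as NaN and excluded from the mean (with a warning).
    """
    P = np.asarray(prob_matrix, dtype=float)
    y = np.asarray(true_labels)
    if P.ndim != 2 or P.shape[0] != y.shape[0]:
        raise ValueError("prob_matrix rows must align with true_labels")
    n_classes = P.shape[1]
    aucs = np.full(n_classes, np.nan)
    for c in range(n_classes):
        pos = y == c
        n_pos = int(pos.sum())
        n_neg = int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            continue
        ranks = rankdata(P[:, c])  # midranks handle ties
        aucs[c] = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    defined = ~np.isnan(aucs)
    if not defined.all():
        undefined = [CLASS_NAMES[c] if n_classes == N_CLASSES else str(c)
                     for c in np.flatnonzero(~defined)]
        warnings.warn(f"AUC undefined (no positives or no negatives) for: {undefined}")
    if not defined.any():
        raise ValueError("AUC undefined for every class")
    return aucs, float(np.nanmean(aucs))


def confusion_row_proportions(
    pred_labels: Sequence[int], true_labels: Sequence[int], n_classes: int = N_CLASSES
) -> np.ndarray:
    """``C[t][p] = count(true=t, pred=p) / count(true=t)``; empty rows are zero."""
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    counts = np.zeros((n_classes, n_classes))
    np.add.at(counts, (true, pred), 1.0)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(row_tot > 0, counts / np.maximum(row_tot, 1), 0.0)
    return out


def grouped_accuracy(
    pred_labels: Sequence[int], true_labels: Sequence[int], groups: Sequence
) -> dict:
    """Accuracy per distinct group value."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    groups = np.asarray(groups)
    if not (len(pred) == len(true) == len(groups)):
        raise ValueError("labels and groups must be aligned")
    out = {}
    for g in pd_unique(groups):
        mask = groups == g
        out[g] = float(np.mean(pred[mask] == true[mask]))
    return out


def pd_unique(values: np.ndarray) -> list:
    """Distinct values in first-appearance order."""
    seen: dict = {}
    for v in values.tolist():
        seen.setdefault(v, None)
    return list(seen)


def age_groups(ages_months: Sequence[float], cutoffs: Sequence[float] = (12.0,)) -> np.ndarray:
    """Bin ages at the given cutoffs; default yields '<12' and '>=12' months."""
    ages = np.asarray(ages_months, dtype=float)
    cutoffs = sorted(cutoffs)
    edges = [-np.inf, *cutoffs, np.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(lo):
            labels.append(f"<{hi:g}")
        elif np.isinf(hi):
            labels.append(f">={lo:g}")
        else:
            labels.append(f"[{lo:g},{hi:g})")
    idx = np.digitize(ages, cutoffs)
    return np.array([labels[i] for i in idx])


@dataclass
class EvalReport:
    accuracy: float
    auc_per_class: np.ndarray
    auc_mean: float
    confusion: np.ndarray
    group_accuracy: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc_per_class": {
                CLASS_NAMES[c]: (None if np.isnan(a) else float(a))
                for c, a in enumerate(self.auc_per_class)
            },
            "auc_mean": self.auc_mean,
            "confusion_row_proportions": self.confusion.tolist(),
            "group_accuracy": {str(k): v for k, v in self.group_accuracy.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_predictions(
    prob_matrix: np.ndarray,
    true_labels: Sequence[int],
    group_maps: Mapping[str, Sequence] | None = None,
) -> EvalReport:
    """Full report from an N x 5 probability matrix and final labels."""
    P = np.asarray(prob_matrix, dtype=float)
    true = np.asarray(true_labels, dtype=int)
    pred = P.argmax(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aucs, auc_mean = auc_ovr(P, true)
    report = EvalReport(
        accuracy=multiclass_accuracy(pred, true),
        auc_per_class=aucs,
        auc_mean=auc_mean,
        confusion=confusion_row_proportions(pred, true),
    )
    for name, groups in (group_maps or {}).items():
        for g, acc in grouped_accuracy(pred, true, groups).items():
            report.group_accuracy[f"{name}={g}"] = acc
    return report


# ---------------------------------------------------------------------------
# Reader identifiability
# ---------------------------------------------------------------------------

def reader_identifiability(
    model,
    data,
    test_image_ids,
    pipe=None,
    pair=None,
) -> dict:
    """Do reader-conditional streams carry reader identity?

    Picks the within-site initial-reader pair with the largest minimum
    Bayes distinguishability margin (unless ``pair`` is given), restricts to
    their shared held-out images where their initial reads *disagree* —
    concordant reads carry no reader-specific signal, only truth-confidence
    — and scores each stream by the mean probability it assigns to the
    observed labels.  A reader-faithful model gives each reader's labels a
    higher score under that reader's own stream than under the partner's.

    Returns a dict with the pair ids, the discordant sample size, and for
    each reader the own-stream and other-stream soft agreements.
    """
    from .interface import predict_matrix
    from .panel_sim import Phase, reader_distinguishability

    if pair is None:
        initial = data.initial_profiles
        site_pairs = [
            (initial[2 * i], initial[2 * i + 1]) for i in range(len(initial) // 2)
        ]
        pair = max(site_pairs, key=lambda p: min(reader_distinguishability(*p)))
    pa, pb = pair
    idx = data.reader_index
    test_ids = set(test_image_ids)
    labels: dict[str, dict[str, int]] = {pa.reader_id: {}, pb.reader_id: {}}
    for rec in data.annotations:
        if rec.phase is Phase.INITIAL and rec.image_id in test_ids and rec.reader_id in labels:
            labels[rec.reader_id][rec.image_id] = int(rec.label)
    shared = sorted(set(labels[pa.reader_id]) & set(labels[pb.reader_id]))
    discordant = [i for i in shared if labels[pa.reader_id][i] != labels[pb.reader_id][i]]
    if not discordant:
        raise ValueError("no discordant shared held-out images for the selected pair")
    imgs = [data.image_by_id(i) for i in discordant]
    P = {
        p.reader_id: predict_matrix(model, imgs, pipe, [idx[p.reader_id]])
        for p in (pa, pb)
    }
    report: dict = {
        "pair": (pa.reader_id, pb.reader_id),
        "n_discordant": len(discordant),
        "streams": {},
    }
    for tgt, oth in ((pa, pb), (pb, pa)):
        y = [labels[tgt.reader_id][i] for i in discordant]
        own = float(np.mean([P[tgt.reader_id][j, y[j]] for j in range(len(y))]))
        other = float(np.mean([P[oth.reader_id][j, y[j]] for j in range(len(y))]))
        report["streams"][tgt.reader_id] = {
            "own_agreement": own,
            "other_agreement": other,
            "identifiable": own > other,
        }
    return report


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def gradcam(
    model: ReaderNet,
    image_tensor: np.ndarray,
    target_class: int,
    reader_id: int | None = None,
) -> np.ndarray:
    """Saliency heatmap on the input grid, in [0, 1].

    The head of the model is GAP -> (optional reader modulation) -> linear,
    so the gradient of the target-class logit with respect to the final
    feature map is spatially constant; the channel weights are that gradient
    spatially averaged.  The weighted channel sum is rectified, upsampled
    bilinearly to the input size, and normalized by its maximum (an all-zero
    map stays zero).
    """
    x = np.asarray(image_tensor, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[0] != 1:
        raise ValueError("gradcam expects a single image tensor")
    target_class = int(target_class)
    rids = None if reader_id is None else np.array([int(reader_id)])
    model.predict_proba(x, rids, capture=True)
    feat = model.last_feature_map[0]  # (C, h, w)
    h, w = feat.shape[1:]
    # d logit_c / d feat = head.W[c] * modulation / (h*w), constant in space
    weights = model.head.params["W"][target_class].astype(np.float64)
    if rids is not None and model.last_modulation is not None:
        weights = weights * model.last_modulation[0]
    alphas = weights / (h * w)
    cam = np.maximum(np.tensordot(alphas, feat.astype(np.float64), axes=(0, 0)), 0.0)
    H, W = x.shape[2], x.shape[3]
    cam = sktransform.resize(cam, (H, W), order=1, preserve_range=True, anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return cam.astype(np.float32)
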