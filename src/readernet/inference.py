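"""Per-reader prediction and unweighted-mean ensemble aggregation.

A reader-embedding model makes one prediction per reader for every image
(every reader, including those who never annotated it).  The final
classification is the arithmetic column mean of the per-reader probability
rows — an ensemble of reader-conditional predictors sharing one backbone.
Argmax ties break toward the lowest canonical class index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .labels import ClassLabel, CLASS_NAMES
from .model import ReaderNet
from .training import PipelineConfig, preprocess_eval

__all__ = [
    "AggregatedPrediction",
    "predict_panel",
    "aggregate_mean",
    "classify",
    "predictions_frame",
]


@dataclass(frozen=True)
class AggregatedPrediction:
    probs: np.ndarray
    label: ClassLabel


def predict_panel(
    model: ReaderNet,
    image,
    reader_ids: Sequence[int],
    pipe: PipelineConfig | None = None,
) -> np.ndarray:
    """R x 5 row-stochastic matrix of per-reader predictions for one image.

    ``image`` may be a raw pixel array (preprocessed once with the eval
    pipeline) or an already-preprocessed ``(C, H, W)`` tensor when ``pipe``
    is None and the channel count matches.
    """
    if not model.spec.use_reader_embeddings:
        raise ValueError("panel prediction requires a reader-embedding model")
    reader_ids = np.asarray(reader_ids, dtype=np.int64)
    if reader_ids.size == 0:
        raise ValueError("reader_ids must be nonempty")
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = preprocess_eval(x, pipe)
    batch = np.repeat(x[None], reader_ids.size, axis=0)
    return model.predict_proba(batch, reader_ids)


def aggregate_mean(prediction_matrix: np.ndarray) -> AggregatedPrediction:
    """Unweighted column mean of per-reader rows, with lowest-index tie-break."""
    P = np.asarray(prediction_matrix, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError("prediction matrix must have at least one row")
    probs = P.mean(axis=0)
    return AggregatedPrediction(probs=probs, label=ClassLabel(int(np.argmax(probs))))


def classify(
    model: ReaderNet,
    image,
    reader_ids: Sequence[int] | None = None,
    pipe: PipelineConfig | None = None,
) -> ClassLabel:
    """Final class for one image.

    Reader-embedding models aggregate over ``reader_ids`` (default: all
    readers); baseline models predict directly.
    """
    x = np.asarray(image, dtype=np.float32)
    if model.spec.use_reader_embeddings:
        if reader_ids is None:
            reader_ids = np.arange(model.spec.n_readers)
        return aggregate_mean(predict_panel(model, x, reader_ids, pipe)).label
    if x.ndim == 2:
        x = preprocess_eval(x, pipe)
    probs = model.predict_proba(x[None] if x.ndim == 3 else x)
    return ClassLabel(int(np.argmax(probs[0])))


def predictions_frame(image_ids: Sequence[str], reader_ids: Sequence[str], P: np.ndarray) -> pd.DataFrame:
    """Long-format per-reader prediction table for CSV export."""
    cols = [f"p_{name.lower()}" for name in CLASS_NAMES]
    rows = []
    k = 0
    for image_id in image_ids:
        for reader in reader_ids:
            rows.append({"image_id": image_id, "reader_id": reader, **dict(zip(cols, P[k]))})
            k += 1
    return pd.DataFrame(rows)
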