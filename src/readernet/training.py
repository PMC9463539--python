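"""Training machinery: sampling, augmentation, schedule, and the loop.

Two training targets are supported.  ``FINAL_LABEL`` is the conventional
setup: every image is paired with its arbitrated final label.
``READER_LABEL`` trains the reader-embedding model on individual
annotations: each epoch samples *one* annotation (a reader and that
reader's label) per training image, so both variants perform the same
number of weight updates per epoch.

The augmentation pipeline mirrors common radiograph practice: resize,
random resized crop, horizontal flip, optional affine (rotation/shear) and
brightness/contrast jitter, channel replication and per-channel
normalization.  The full-scale profile is 300x300 -> 224x224 with ImageNet
statistics; a toy profile operates at the synthetic images' native size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from skimage import transform as sktransform

from . import nn
from .labels import ClassLabel
from .model import ReaderNet
from .panel_sim import AnnotationRecord, DatasetSplit, PanelDataset

__all__ = [
    "TrainTarget",
    "TrainConfig",
    "PipelineConfig",
    "toy_pipeline",
    "HistoryRecord",
    "epoch_sample",
    "augment_train",
    "preprocess_eval",
    "lr_at_epoch",
    "Trainer",
    "train_loop",
]


class TrainTarget(str, Enum):
    FINAL_LABEL = "FINAL_LABEL"
    READER_LABEL = "READER_LABEL"


@dataclass
class PipelineConfig:
    """Geometry and photometry of the input pipeline."""

    resize_to: int = 300
    crop: int = 224
    channels: int = 3
    mean: tuple[float, ...] = (0.485, 0.456, 0.406)
    std: tuple[float, ...] = (0.229, 0.224, 0.225)
    scale_range: tuple[float, float] = (0.6, 1.0)  # crop area fraction
    ratio_range: tuple[float, float] = (0.75, 4.0 / 3.0)
    p_flip: float = 0.5
    rotation_deg: float = 10.0
    shear_deg: float = 10.0
    brightness: float = 0.1
    contrast: float = 0.2


def toy_pipeline(size: int = 64) -> PipelineConfig:
    """Desk-scale pipeline: native-size grayscale, mild crops."""
    return PipelineConfig(
        resize_to=size,
        crop=size,
        channels=1,
        mean=(0.5,),
        std=(0.25,),
        scale_range=(0.7, 1.0),
        rotation_deg=8.0,
        shear_deg=6.0,
    )


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 150
    base_lr_conv: float = 0.05
    base_lr_fc: float = 0.05
    base_lr_proj: float = 0.05
    base_lr_emb: float = 0.30
    wd_conv: float = 1e-4
    wd_fc: float = 1e-4
    wd_proj: float = 1e-4
    dropout: float = 0.1
    p_affine: float = 0.3
    p_color: float = 0.3
    max_norm: float | None = None
    seed: int = 0
    target: TrainTarget = TrainTarget.FINAL_LABEL
    momentum: float = 0.9
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        self.target = TrainTarget(self.target)
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for name in ("base_lr_conv", "base_lr_fc", "base_lr_proj", "base_lr_emb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class HistoryRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_accuracy: float
    lr_scale: float = 1.0


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def epoch_sample(
    annotations: Sequence[AnnotationRecord],
    train_images: Sequence[str],
    rng: np.random.Generator,
) -> list[tuple[str, str, ClassLabel]]:
    """One (image, reader, label) triple per training image, shuffled.

    The annotation is drawn uniformly among all of the image's records
    (initial, arbitration, consensus and QC reads alike), so readers who
    annotated an image more often in different phases are weighted by their
    record count.
    """
    by_image: dict[str, list[AnnotationRecord]] = {}
    for rec in annotations:
        by_image.setdefault(rec.image_id, []).append(rec)
    sample: list[tuple[str, str, ClassLabel]] = []
    for image_id in train_images:
        recs = by_image.get(image_id)
        if not recs:
            raise ValueError(f"image {image_id!r} has no annotations")
        rec = recs[int(rng.integers(len(recs)))]
        sample.append((image_id, rec.reader_id, rec.label))
    order = rng.permutation(len(sample))
    return [sample[i] for i in order]


# ---------------------------------------------------------------------------
# Input pipeline
# ---------------------------------------------------------------------------

def _resize(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape == (size, size):
        return img.astype(np.float32)
    out = sktransform.resize(
        img, (size, size), order=1, preserve_range=True, anti_aliasing=img.shape[0] > size
    )
    return out.astype(np.float32)


def _finalize(img: np.ndarray, pipe: PipelineConfig) -> np.ndarray:
    """Replicate channels and normalize: (H, W) -> (C, crop, crop)."""
    mean = np.asarray(pipe.mean, dtype=np.float32)[:, None, None]
    std = np.asarray(pipe.std, dtype=np.float32)[:, None, None]
    stack = np.repeat(img[None], pipe.channels, axis=0)
    return ((stack - mean) / std).astype(np.float32)


def preprocess_eval(pixels: np.ndarray, pipe: PipelineConfig | None = None) -> np.ndarray:
    """Deterministic eval path: resize, center crop, replicate, normalize."""
    pipe = pipe or PipelineConfig()
    img = _resize(np.asarray(pixels, dtype=np.float32), pipe.resize_to)
    off = (pipe.resize_to - pipe.crop) // 2
    img = img[off : off + pipe.crop, off : off + pipe.crop]
    return _finalize(img, pipe)


def augment_train(
    pixels: np.ndarray,
    p_affine: float,
    p_color: float,
    rng: np.random.Generator,
    pipe: PipelineConfig | None = None,
) -> np.ndarray:
    """Stochastic training path; deterministic given the generator state."""
    pipe = pipe or PipelineConfig()
    img = _resize(np.asarray(pixels, dtype=np.float32), pipe.resize_to)
    H = W = pipe.resize_to

    # random resized crop
    lo, hi = pipe.scale_range
    area_frac = float(rng.uniform(lo, hi))
    log_r = rng.uniform(math.log(pipe.ratio_range[0]), math.log(pipe.ratio_range[1]))
    ratio = math.exp(log_r)
    area = area_frac * H * W
    cw = min(W, max(1, int(round(math.sqrt(area * ratio)))))
    ch = min(H, max(1, int(round(math.sqrt(area / ratio)))))
    y0 = int(rng.integers(0, H - ch + 1))
    x0 = int(rng.integers(0, W - cw + 1))
    img = _resize(img[y0 : y0 + ch, x0 : x0 + cw], pipe.crop)

    if rng.random() < pipe.p_flip:
        img = img[:, ::-1].copy()

    if rng.random() < p_affine:
        rot = math.radians(rng.uniform(-pipe.rotation_deg, pipe.rotation_deg))
        shear = math.radians(rng.uniform(-pipe.shear_deg, pipe.shear_deg))
        c = pipe.crop / 2.0
        tf = (
            sktransform.AffineTransform(translation=(-c, -c))
            + sktransform.AffineTransform(rotation=rot, shear=shear)
            + sktransform.AffineTransform(translation=(c, c))
        )
        img = sktransform.warp(img, tf.inverse, order=1, mode="edge", preserve_range=True)
        img = img.astype(np.float32)

    if rng.random() < p_color:
        contrast = float(rng.uniform(1.0 - pipe.contrast, 1.0 + pipe.contrast))
        brightness = float(rng.uniform(-pipe.brightness, pipe.brightness))
        img = np.clip((img - 0.5) * contrast + 0.5 + brightness, 0.0, 1.0).astype(np.float32)

    return _finalize(img, pipe)


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

def lr_at_epoch(base: float, epoch: int) -> float:
    """Step schedule: full rate to epoch 49, halved at 50, halved again at 100."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    if epoch < 50:
        return base
    if epoch < 100:
        return base / 2.0
    return base / 4.0


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

class Trainer:
    """Deterministic single-process trainer for both model variants.

    A validation fold is carved out of the *training* patients (the test
    split is never touched).  Validation metrics are always computed against
    final labels: the baseline variant predicts directly, while the
    reader-label variant predicts conditional on a fixed per-image reader
    sampled once from the image's annotators — so its validation curve
    reflects the noisier per-reader task, comparable epoch-by-epoch with
    the baseline's.
    """

    def __init__(
        self,
        model: ReaderNet,
        data: PanelDataset,
        split: DatasetSplit,
        cfg: TrainConfig,
        pipeline: PipelineConfig | None = None,
        step_callback: Callable[[ReaderNet], None] | None = None,
    ) -> None:
        if cfg.target is TrainTarget.READER_LABEL and not model.spec.use_reader_embeddings:
            raise ValueError("READER_LABEL training requires a reader-embedding model")
        self.model = model
        self.data = data
        self.cfg = cfg
        if cfg.max_norm is not None:
            model.spec.max_norm = cfg.max_norm
        self.pipe = pipeline or toy_pipeline(data.images[0].pixels.shape[0])
        self.step_callback = step_callback
        self.reader_index = data.reader_index

        root = np.random.SeedSequence(cfg.seed)
        ss_val, ss_epochs = root.spawn(2)
        val_rng = np.random.default_rng(ss_val)
        self._epoch_ss = ss_epochs

        train_pool = sorted(
            im.image_id for im in data.images if im.patient_id in split.train_patients
        )
        train_patients = sorted({data.image_by_id(i).patient_id for i in train_pool})
        n_val = max(1, int(round(cfg.val_fraction * len(train_patients))))
        val_patients = set(
            val_rng.choice(train_patients, size=min(n_val, len(train_patients) - 1), replace=False)
        )
        self.train_ids = [
            i for i in train_pool if data.image_by_id(i).patient_id not in val_patients
        ]
        self.val_ids = [i for i in train_pool if data.image_by_id(i).patient_id in val_patients]
        if not self.train_ids or not self.val_ids:
            raise ValueError("training and validation folds must both be nonempty")

        self._train_annotations = [
            rec for rec in data.annotations if rec.image_id in set(self.train_ids)
        ]
        # cache resized source images and preprocessed validation tensors
        self._source = {
            i: _resize(data.image_by_id(i).pixels, self.pipe.resize_to) for i in self.train_ids
        }
        self._val_x = np.stack(
            [preprocess_eval(data.image_by_id(i).pixels, self.pipe) for i in self.val_ids]
        )
        self._val_y = np.array([int(data.final_by_id(i).label) for i in self.val_ids])
        ann_by_image: dict[str, list[AnnotationRecord]] = {}
        for rec in data.annotations:
            ann_by_image.setdefault(rec.image_id, []).append(rec)
        self._val_reader_ids = np.array(
            [
                self.reader_index[
                    ann_by_image[i][int(val_rng.integers(len(ann_by_image[i])))].reader_id
                ]
                for i in self.val_ids
            ]
        )

        groups = model.param_groups()
        opt_groups = {
            "conv": (groups["conv"], cfg.base_lr_conv, cfg.wd_conv),
            "fc": (groups["fc"], cfg.base_lr_fc, cfg.wd_fc),
        }
        if "proj" in groups:
            opt_groups["proj"] = (groups["proj"], cfg.base_lr_proj, cfg.wd_proj)
            opt_groups["emb"] = (groups["emb"], cfg.base_lr_emb, 0.0)
        self.optimizer = nn.SGD(opt_groups, momentum=cfg.momentum)
        self.history: list[HistoryRecord] = []
        self.steps_per_epoch = math.ceil(len(self.train_ids) / cfg.batch_size)
        self._epoch = 0

    # -- epoch mechanics ----------------------------------------------------

    def _epoch_pairs(self, rng: np.random.Generator) -> list[tuple[str, int | None, int]]:
        if self.cfg.target is TrainTarget.READER_LABEL:
            triples = epoch_sample(self._train_annotations, self.train_ids, rng)
            return [(i, self.reader_index[r], int(lab)) for i, r, lab in triples]
        order = rng.permutation(len(self.train_ids))
        return [
            (self.train_ids[i], None, int(self.data.final_by_id(self.train_ids[i]).label))
            for i in order
        ]

    def run_epochs(self, n_epochs: int) -> list[HistoryRecord]:
        cfg = self.cfg
        for _ in range(n_epochs):
            epoch = self._epoch
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=self._epoch_ss.entropy, spawn_key=(1, epoch))
            )
            pairs = self._epoch_pairs(rng)
            scale = lr_at_epoch(1.0, epoch)
            losses = []
            for b0 in range(0, len(pairs), cfg.batch_size):
                batch = pairs[b0 : b0 + cfg.batch_size]
                xs = np.stack(
                    [
                        augment_train(
                            self._source[i], cfg.p_affine, cfg.p_color, rng, self.pipe
                        )
                        for i, _, _ in batch
                    ]
                )
                ys = np.array([lab for _, _, lab in batch])
                rids = None
                if cfg.target is TrainTarget.READER_LABEL:
                    rids = np.array([r for _, r, _ in batch])
                logits = self.model.forward(xs, rids, train=True)
                loss, dlogits = nn.softmax_cross_entropy(logits, ys)
                if not math.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, step {b0 // cfg.batch_size}"
                    )
                losses.append(loss)
                self.optimizer.zero_grad()
                self.model.backward(dlogits)
                self.optimizer.step(scale)
                self.model.apply_max_norm()
                if self.step_callback is not None:
                    self.step_callback(self.model)
            val_loss, val_acc = self._validate()
            self.history.append(
                HistoryRecord(epoch, float(np.mean(losses)), val_loss, val_acc, scale)
            )
            self._epoch += 1
        return self.history

    def _validate(self) -> tuple[float, float]:
        cfg = self.cfg
        n = len(self.val_ids)
        losses, correct = [], 0
        for b0 in range(0, n, cfg.batch_size):
            xs = self._val_x[b0 : b0 + cfg.batch_size]
            ys = self._val_y[b0 : b0 + cfg.batch_size]
            rids = None
            if cfg.target is TrainTarget.READER_LABEL:
                rids = self._val_reader_ids[b0 : b0 + cfg.batch_size]
            logits = self.model.forward(xs, rids, train=False)
            loss, _ = nn.softmax_cross_entropy(logits, ys)
            losses.append(loss * len(ys))
            correct += int((logits.argmax(axis=1) == ys).sum())
        return float(np.sum(losses) / n), correct / n


def train_loop(
    model: ReaderNet,
    data: PanelDataset,
    split: DatasetSplit,
    cfg: TrainConfig,
    pipeline: PipelineConfig | None = None,
    step_callback: Callable[[ReaderNet], None] | None = None,
) -> tuple[ReaderNet, list[HistoryRecord]]:
    """Train for ``cfg.epochs`` epochs; returns the model and its history."""
    trainer = Trainer(model, data, split, cfg, pipeline, step_callback)
    history = trainer.run_epochs(cfg.epochs)
    return model, history
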