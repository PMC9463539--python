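"""The desk-scale comparison experiment, packaged as one reusable call.

A trial simulates a panel-annotated dataset (~1,500 images at 64x64, six
initial readers and two arbitrators with heterogeneous confusion matrices),
splits 20% of patients out, trains the baseline (final labels) and the
reader-embedding variant (individual reader labels) for 30 epochs each, and
evaluates both on the held-out patients: aggregated and per-reader-
conditional accuracy, one-vs-rest AUC, validation curves, reader
identifiability, and Grad-CAM localization against the generator's lesion
masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import ClassLabel
from .panel_sim import PanelDataset, DatasetSplit, build_panel_dataset, split_by_patient
from .model import ModelSpec, ReaderNet, build_model
from .training import HistoryRecord, TrainConfig, Trainer, preprocess_eval, toy_pipeline
from .interface import predict_matrix
from .evaluation import (
    evaluate_predictions,
    gradcam,
    multiclass_accuracy,
    reader_identifiability,
)

__all__ = ["DeskTrial", "run_desk_trial"]


@dataclass
class DeskTrial:
    seed: int
    data: PanelDataset
    split: DatasetSplit
    baseline: ReaderNet
    reader_model: ReaderNet
    baseline_history: list[HistoryRecord]
    reader_history: list[HistoryRecord]
    baseline_accuracy: float
    aggregated_accuracy: float
    baseline_auc_mean: float
    aggregated_auc_mean: float
    per_reader_accuracy: dict[str, float]
    identifiability: dict
    gradcam_hits: int
    gradcam_total: int
    final_vs_truth_accuracy: float
    test_image_ids: list[str] = field(default_factory=list)

    @property
    def mean_reader_conditional_accuracy(self) -> float:
        return float(np.mean(list(self.per_reader_accuracy.values())))


def run_desk_trial(
    seed: int,
    *,
    n_patients: int = 1440,
    image_size: int = 64,
    epochs: int = 30,
    n_initial_readers: int = 6,
    n_arbitrators: int = 2,
) -> DeskTrial:
    """Run one full desk-scale comparison; deterministic in ``seed``."""
    root = np.random.SeedSequence(seed)
    sim_seed, split_seed, train_seed = (
        int(np.random.default_rng(s).integers(2**31)) for s in root.spawn(3)
    )
    data = build_panel_dataset(
        n_patients=n_patients,
        n_initial_readers=n_initial_readers,
        n_arbitrators=n_arbitrators,
        seed=sim_seed,
        image_size=image_size,
        site_prior_adjust=False,
    )
    split = split_by_patient(data.images, 0.2, split_seed)
    test_images = [im for im in data.images if im.patient_id in split.test_patients]
    y_final = np.array([int(data.final_by_id(im.image_id).label) for im in test_images])
    y_truth = np.array([int(im.true_class) for im in test_images])
    pipe = toy_pipeline(image_size)
    R = len(data.profiles)

    models: dict[str, ReaderNet] = {}
    histories: dict[str, list[HistoryRecord]] = {}
    for name, with_readers in (("baseline", False), ("reader", True)):
        spec = ModelSpec(
            backbone="TOY_CNN",
            n_readers=R,
            use_reader_embeddings=with_readers,
            dropout=0.1,
            max_norm=4.0,
            activation="IDENTITY",
        )
        cfg = TrainConfig(
            epochs=epochs,
            seed=train_seed,
            target="READER_LABEL" if with_readers else "FINAL_LABEL",
            dropout=0.1,
            max_norm=4.0,
        )
        model = build_model(spec, seed=train_seed)
        trainer = Trainer(model, data, split, cfg, pipe)
        histories[name] = trainer.run_epochs(epochs)
        models[name] = model

    P_base = predict_matrix(models["baseline"], test_images, pipe, None)
    P_agg = predict_matrix(models["reader"], test_images, pipe, np.arange(R))
    rep_base = evaluate_predictions(P_base, y_final)
    rep_agg = evaluate_predictions(P_agg, y_final)
    per_reader = {
        data.profiles[r].reader_id: multiclass_accuracy(
            predict_matrix(models["reader"], test_images, pipe, [r]).argmax(1), y_final
        )
        for r in range(R)
    }
    ident = reader_identifiability(
        models["reader"], data, [im.image_id for im in test_images], pipe
    )

    # Grad-CAM localization on correctly classified consolidation images
    cons = [im for im in test_images if im.true_class is ClassLabel.CONSOLIDATION]
    P_cons = predict_matrix(models["baseline"], cons, pipe, None)
    hits = total = 0
    for im, p in zip(cons, P_cons):
        if int(p.argmax()) != int(ClassLabel.CONSOLIDATION):
            continue
        total += 1
        heat = gradcam(
            models["baseline"], preprocess_eval(im.pixels, pipe), int(ClassLabel.CONSOLIDATION)
        )
        if heat[im.blob_mask].mean() > heat[~im.blob_mask].mean():
            hits += 1

    return DeskTrial(
        seed=seed,
        data=data,
        split=split,
        baseline=models["baseline"],
        reader_model=models["reader"],
        baseline_history=histories["baseline"],
        reader_history=histories["reader"],
        baseline_accuracy=rep_base.accuracy,
        aggregated_accuracy=rep_agg.accuracy,
        baseline_auc_mean=rep_base.auc_mean,
        aggregated_auc_mean=rep_agg.auc_mean,
        per_reader_accuracy=per_reader,
        identifiability=ident,
        gradcam_hits=hits,
        gradcam_total=total,
        final_vs_truth_accuracy=float(np.mean(y_final == y_truth)),
        test_image_ids=[im.image_id for im in test_images],
    )
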