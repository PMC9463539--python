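"""Configuration, manifest I/O, and end-to-end experiment orchestration.

One experiment = one directory.  A YAML config (simulation, model,
training, evaluation sections plus a root seed) drives: simulate a panel
dataset -> patient-level split -> train the baseline (final labels) and the
reader-embedding variant (reader labels) -> evaluate both on the held-out
patients -> write a comparison report.  Every stage draws its randomness
from a named substream of the root seed, so a run is reproducible from
(config, seed) alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .labels import CLASS_NAMES, parse_label
from .panel_sim import (
    AnnotationRecord,
    FinalLabel,
    PanelDataset,
    Phase,
    Provenance,
    build_panel_dataset,
    split_by_patient,
)
from .model import ActivationKind, BackboneKind, ModelSpec, build_model, save_model
from .training import TrainConfig, TrainTarget, Trainer, preprocess_eval, toy_pipeline
from .evaluation import age_groups, evaluate_predictions, multiclass_accuracy

logger = logging.getLogger("readernet")

__all__ = [
    "AnnotationParseError",
    "ExperimentConfig",
    "RunManifest",
    "read_annotations",
    "write_annotations",
    "read_finals",
    "write_finals",
    "write_images",
    "write_history",
    "config_hash",
    "run_experiment",
]

MANIFEST_COLUMNS = [
    "image_id",
    "patient_id",
    "site",
    "age_months",
    "reader_id",
    "role",
    "phase",
    "label",
    "true_class",
]


class AnnotationParseError(ValueError):
    """Raised on malformed manifest rows; carries offending line numbers."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in problems)
        super().__init__(f"malformed annotation manifest: {lines}")


def read_annotations(path) -> list[AnnotationRecord]:
    """Read an annotation manifest CSV into validated records.

    Malformed rows (unknown labels or phases) are rejected with their
    1-based file line numbers; missing columns fail immediately.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("image_id", "reader_id", "phase", "label") if c not in df.columns]
    if missing:
        raise AnnotationParseError([(1, f"missing columns {missing}")])
    records, problems = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            records.append(
                AnnotationRecord(
                    image_id=str(row.image_id),
                    reader_id=str(row.reader_id),
                    label=parse_label(str(row.label)),
                    phase=Phase(str(row.phase)),
                )
            )
        except ValueError as exc:
            problems.append((line_no, str(exc)))
    if problems:
        raise AnnotationParseError(problems)
    return records


def write_annotations(data: PanelDataset, path) -> None:
    data.manifest_frame()[MANIFEST_COLUMNS].to_csv(path, index=False)


def write_finals(data: PanelDataset, path) -> None:
    data.finals_frame().to_csv(path, index=False)


def read_finals(path) -> list[FinalLabel]:
    df = pd.read_csv(path, dtype=str)
    return [
        FinalLabel(str(r.image_id), parse_label(str(r.label)), Provenance(str(r.provenance)))
        for r in df.itertuples(index=False)
    ]


def write_images(images, out_dir) -> None:
    """Write each synthetic image as an 8-bit grayscale PNG ``<image_id>.png``."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for im in images:
        arr = np.clip(im.pixels * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out_dir / f"{im.image_id}.png")


def write_history(history, path) -> None:
    pd.DataFrame(
        {
            "epoch": [h.epoch for h in history],
            "train_loss": [h.train_loss for h in history],
            "val_loss": [h.val_loss for h in history],
            "val_accuracy": [h.val_accuracy for h in history],
        }
    ).to_csv(path, index=False)


def load_panel_dir(path) -> PanelDataset:
    """Reconstruct a dataset from a directory written by ``simulate``.

    Expects ``annotations.csv`` (full manifest), ``final_labels.csv`` and an
    ``images/`` directory of grayscale PNGs.  Reader error profiles are not
    serialized, so placeholder identity profiles carry the ids and roles;
    everything training and prediction need (images, annotations, finals,
    reader indexing) is restored exactly.
    """
    from PIL import Image

    from .panel_sim import ReaderProfile, ReaderRole, SynthImage

    path = Path(path)
    manifest = pd.read_csv(path / "annotations.csv")
    records = read_annotations(path / "annotations.csv")
    finals = read_finals(path / "final_labels.csv")

    meta = manifest.drop_duplicates("image_id").set_index("image_id")
    images = []
    for image_id, row in meta.iterrows():
        arr = np.asarray(Image.open(path / "images" / f"{image_id}.png"), dtype=np.float32)
        images.append(
            SynthImage(
                image_id=str(image_id),
                patient_id=str(row["patient_id"]),
                site=str(row["site"]),
                age_months=float(row["age_months"]),
                true_class=parse_label(str(row["true_class"])),
                pixels=arr / 255.0,
            )
        )
    roles = manifest.drop_duplicates("reader_id").set_index("reader_id")["role"]
    profiles = [
        ReaderProfile(str(rid), ReaderRole(str(role)), np.eye(5), age_noise_slope=0.0)
        for rid, role in roles.sort_index().items()
    ]
    return PanelDataset(images, records, finals, profiles, seed=-1)


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def config_hash(config: ExperimentConfig) -> str:
    """Stable under key reordering: hash of the canonical JSON form."""
    canon = json.dumps(asdict(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def desk_config(seed: int = 0, **sim_overrides) -> ExperimentConfig:
    """The desk-scale experiment profile used throughout the package."""
    sim = {
        "n_patients": 1440,
        "image_size": 64,
        "n_initial_readers": 6,
        "n_arbitrators": 2,
        "images_per_patient_dist": {1: 0.96, 2: 0.04},
        "site_prior_adjust": False,
    }
    sim.update(sim_overrides)
    return ExperimentConfig(
        seed=seed,
        simulation=sim,
        model={"backbone": "TOY_CNN", "reader_emb_dim": 32, "activation": "IDENTITY",
               "dropout": 0.1, "max_norm": 4.0},
        training={"batch_size": 32, "epochs": 30, "p_affine": 0.3, "p_color": 0.3},
        evaluation={"group_keys": ["site"], "age_bins": [12.0]},
    )


@dataclass
class RunManifest:
    run_id: str
    config_hash: str
    artifacts: dict
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _stage_seed(root: int, stage: int) -> int:
    return int(
        np.random.default_rng(np.random.SeedSequence(root, spawn_key=(stage,))).integers(2**31)
    )


def predict_matrix(model, images, pipe, reader_ids=None, batch_size=64) -> np.ndarray:
    """N x 5 probabilities: aggregated over readers, or the baseline path."""
    xs = np.stack([preprocess_eval(im.pixels, pipe) for im in images])
    out = []
    if reader_ids is None:
        for b0 in range(0, len(xs), batch_size):
            out.append(model.predict_proba(xs[b0 : b0 + batch_size]))
        return np.concatenate(out)
    reader_ids = np.asarray(reader_ids)
    for b0 in range(0, len(xs), batch_size):
        xb = xs[b0 : b0 + batch_size]
        acc = np.zeros((xb.shape[0], model.spec.n_classes))
        for r in reader_ids:
            rids = np.full(xb.shape[0], int(r), dtype=np.int64)
            acc += model.predict_proba(xb, rids)
        out.append(acc / reader_ids.size)
    return np.concatenate(out)


def run_experiment(config: ExperimentConfig, out_dir, save_images: bool = False) -> RunManifest:
    """Simulate, split, train both variants, evaluate, and write the report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    chash = config_hash(config)
    run_id = f"run-{chash}"
    artifacts: dict[str, str] = {}
    stage = "simulate"
    try:
        sim = dict(config.simulation)
        test_fraction = float(sim.pop("test_fraction", 0.2))
        ipd = sim.pop("images_per_patient_dist", None)
        if ipd is not None:
            ipd = {int(k): float(v) for k, v in ipd.items()}
        data = build_panel_dataset(
            n_patients=int(sim.pop("n_patients", 1440)),
            images_per_patient_dist=ipd,
            n_initial_readers=int(sim.pop("n_initial_readers", 6)),
            n_arbitrators=int(sim.pop("n_arbitrators", 2)),
            prior=sim.pop("prior", None),
            seed=_stage_seed(config.seed, 0),
            **sim,
        )
        write_annotations(data, out_dir / "annotations.csv")
        write_finals(data, out_dir / "final_labels.csv")
        artifacts["annotations"] = "annotations.csv"
        artifacts["final_labels"] = "final_labels.csv"
        if save_images:
            write_images(data.images, out_dir / "images")
            artifacts["images"] = "images/"

        stage = "split"
        split = split_by_patient(data.images, test_fraction, _stage_seed(config.seed, 1))
        test_images = [im for im in data.images if im.patient_id in split.test_patients]

        stage = "train"
        size = data.images[0].pixels.shape[0]
        pipe = toy_pipeline(size)
        mdl_cfg = dict(config.model)
        use_reader = bool(mdl_cfg.pop("use_reader_embeddings", True))
        train_kwargs = dict(config.training)
        results: dict[str, dict] = {}
        histories: dict[str, list] = {}
        models = {}

        variants = [("baseline", False)] + ([("reader_embedding", True)] if use_reader else [])
        for name, with_readers in variants:
            spec = ModelSpec(
                backbone=BackboneKind(mdl_cfg.get("backbone", "TOY_CNN")),
                n_readers=len(data.profiles),
                reader_emb_dim=int(mdl_cfg.get("reader_emb_dim", 32)),
                activation=ActivationKind(mdl_cfg.get("activation", "IDENTITY")),
                max_norm=mdl_cfg.get("max_norm"),
                dropout=float(mdl_cfg.get("dropout", 0.1)),
                use_reader_embeddings=with_readers,
                toy_channels=tuple(mdl_cfg.get("toy_channels", (8, 16, 32))),
            )
            cfg = TrainConfig(
                **train_kwargs,
                seed=_stage_seed(config.seed, 2 if not with_readers else 3),
                target=TrainTarget.READER_LABEL if with_readers else TrainTarget.FINAL_LABEL,
            )
            model = build_model(spec, seed=cfg.seed)
            logger.info("training %s variant (%d epochs)", name, cfg.epochs)
            trainer = Trainer(model, data, split, cfg, pipe)
            history = trainer.run_epochs(cfg.epochs)
            histories[name] = history
            models[name] = model
            write_history(history, out_dir / f"history_{name}.csv")
            save_model(model, out_dir / f"model_{name}.npz")
            (out_dir / f"summary_{name}.txt").write_text(model.summary() + "\n")
            artifacts[f"history_{name}"] = f"history_{name}.csv"
            artifacts[f"model_{name}"] = f"model_{name}.npz"

        stage = "evaluate"
        y_true = np.array([int(data.final_by_id(im.image_id).label) for im in test_images])
        eval_cfg = dict(config.evaluation)
        group_maps = {}
        if "site" in eval_cfg.get("group_keys", ["site"]):
            group_maps["site"] = np.array([im.site for im in test_images])
        bins = eval_cfg.get("age_bins", [12.0])
        group_maps["age"] = age_groups([im.age_months for im in test_images], bins)

        report: dict = {"run_id": run_id, "n_test_images": len(test_images)}
        for name, model in models.items():
            rids = np.arange(model.spec.n_readers) if model.spec.use_reader_embeddings else None
            probs = predict_matrix(model, test_images, pipe, rids)
            rep = evaluate_predictions(probs, y_true, group_maps)
            report[name] = rep.to_dict()
            if model.spec.use_reader_embeddings:
                per_reader = {}
                for r in range(model.spec.n_readers):
                    pr = predict_matrix(model, test_images, pipe, [r])
                    per_reader[data.profiles[r].reader_id] = multiclass_accuracy(
                        pr.argmax(axis=1), y_true
                    )
                report[name]["per_reader_conditional_accuracy"] = per_reader
                report[name]["mean_reader_conditional_accuracy"] = float(
                    np.mean(list(per_reader.values()))
                )
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        artifacts["report"] = "report.json"
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage {stage!r}: {exc}") from exc

    manifest = RunManifest(run_id, chash, artifacts, started, time.time())
    manifest.to_json(out_dir / "run_manifest.json")
    return manifest
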