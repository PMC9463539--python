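"""Random-search successive halving over training hyper-parameters.

A synchronous variant of asynchronous successive halving: ``n_samples``
random configurations are all trained to the first rung (an epoch count);
at each rung the top ``1/eta`` by validation accuracy are promoted to the
next; survivors of the last rung train to the full epoch budget, and the
configuration with the best final metric wins.  Synchronous promotion is
deterministic and exactly accountable, which is what desk-scale searches
need; asynchrony only buys wall-clock efficiency on a cluster.

Ties at a rung break by the metric at earlier rungs, then by draw order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import ActivationKind, ModelSpec
from .training import TrainConfig, TrainTarget, Trainer  # noqa: F401 (Trainer used by adapter)

__all__ = [
    "HpoSpace",
    "TrialStatus",
    "HpoTrial",
    "default_space",
    "sample_config",
    "make_train_config",
    "run_halving",
    "trials_frame",
    "panel_train_fn",
    "DESK_PRESET",
    "PAPER_PRESET",
]

#: Desk-scale search profile used by the package's own experiments.
DESK_PRESET = {"n_samples": 16, "rungs": (2, 4, 8), "budget": 12}
#: Full-scale profile mirroring a 300-trial ASHA run (not desk-runnable).
PAPER_PRESET = {"n_samples": 300, "rungs": (10, 20, 40, 80), "budget": 150}


@dataclass
class HpoSpace:
    """Per-dimension samplers.

    ``log_uniform`` ranges suit learning rates and weight decays;
    ``uniform`` suits dropout and augmentation proportions; ``categorical``
    covers batch size, activation, and the embedding max-norm.
    """

    log_uniform: dict[str, tuple[float, float]] = field(default_factory=dict)
    uniform: dict[str, tuple[float, float]] = field(default_factory=dict)
    categorical: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in {**self.log_uniform, **self.uniform}.items():
            if not lo < hi or (name in self.log_uniform and lo <= 0):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        for name, choices in self.categorical.items():
            if not choices:
                raise ValueError(f"empty categorical set for {name}")


def default_space() -> HpoSpace:
    return HpoSpace(
        log_uniform={
            "base_lr_conv": (1e-5, 1e-1),
            "base_lr_fc": (1e-5, 1e-1),
            "base_lr_proj": (1e-5, 1e-1),
            "base_lr_emb": (1e-5, 1e-1),
            "wd_conv": (1e-6, 1e-1),
            "wd_fc": (1e-6, 1e-1),
            "wd_proj": (1e-6, 1e-1),
        },
        uniform={"dropout": (0.0, 0.5), "p_affine": (0.0, 1.0), "p_color": (0.0, 1.0)},
        categorical={
            "batch_size": [8, 16, 32],
            "activation": [a.value for a in ActivationKind],
            "max_norm": [1.0, 2.0, 4.0, None],
        },
    )


def sample_config(space: HpoSpace, rng: np.random.Generator) -> dict:
    """One independent draw from every dimension of the space."""
    cfg: dict = {}
    for name, (lo, hi) in space.log_uniform.items():
        cfg[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    for name, (lo, hi) in space.uniform.items():
        cfg[name] = float(rng.uniform(lo, hi))
    for name, choices in space.categorical.items():
        cfg[name] = choices[int(rng.integers(len(choices)))]
    return cfg


def make_train_config(sample: dict, **overrides) -> TrainConfig:
    """Build a TrainConfig from a sampled dict, ignoring model-level keys."""
    fields = set(TrainConfig.__dataclass_fields__)
    kwargs = {k: v for k, v in sample.items() if k in fields}
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


class TrialStatus(str, Enum):
    STOPPED = "STOPPED"
    PROMOTED = "PROMOTED"
    COMPLETED = "COMPLETED"
    FAILED = "FAILED"


@dataclass
class HpoTrial:
    trial_id: int
    config: dict
    metrics: dict[int, float] = field(default_factory=dict)  # rung -> val accuracy
    status: TrialStatus = TrialStatus.STOPPED
    epochs_trained: int = 0
    state: object = None


def _sort_key(trial: HpoTrial, rungs_so_far: Sequence[int]):
    # best first: current rung metric, then earlier rungs, then draw order
    return tuple(-trial.metrics.get(r, -np.inf) for r in reversed(rungs_so_far)) + (
        trial.trial_id,
    )


def run_halving(
    space: HpoSpace,
    n_samples: int,
    rungs: Sequence[int] = (10, 20, 40, 80),
    eta: int = 2,
    train_fn: Callable = None,
    rng: np.random.Generator | int = 0,
    budget: int | None = None,
) -> tuple[dict, list[HpoTrial]]:
    """Run the search; returns (best config, all trials).

    ``train_fn(config, target_epoch, state) -> (metric, state)`` must train
    the configuration *incrementally* to ``target_epoch`` total epochs and
    report the validation metric there; ``state`` carries whatever the
    function needs to resume.  A trial whose ``train_fn`` raises is marked
    FAILED and excluded from promotion.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if eta < 2:
        raise ValueError("eta must be >= 2")
    rungs = [int(r) for r in rungs]
    if any(b <= a for a, b in zip(rungs, rungs[1:])) or rungs[0] < 1:
        raise ValueError("rungs must be strictly increasing positive epochs")
    if budget is None:
        budget = rungs[-1]
    if budget < rungs[-1]:
        raise ValueError("budget must be >= the last rung")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    trials = [HpoTrial(i, sample_config(space, rng)) for i in range(n_samples)]
    active = list(trials)
    seen_rungs: list[int] = []
    for k, rung in enumerate(rungs):
        survivors = []
        for t in active:
            try:
                metric, t.state = train_fn(t.config, rung, t.state)
            except Exception:
                t.status = TrialStatus.FAILED
                continue
            t.epochs_trained = rung
            t.metrics[rung] = float(metric)
            survivors.append(t)
        seen_rungs.append(rung)
        survivors.sort(key=lambda t: _sort_key(t, seen_rungs))
        n_promote = max(1, math.ceil(len(survivors) / eta)) if survivors else 0
        for t in survivors[:n_promote]:
            t.status = TrialStatus.PROMOTED
        for t in survivors[n_promote:]:
            t.status = TrialStatus.STOPPED
        active = survivors[:n_promote]
        if not active:
            raise RuntimeError("all trials failed")

    for t in active:
        if budget > rungs[-1]:
            try:
                metric, t.state = train_fn(t.config, budget, t.state)
            except Exception:
                t.status = TrialStatus.FAILED
                continue
            t.epochs_trained = budget
            t.metrics[budget] = float(metric)
        t.status = TrialStatus.COMPLETED

    completed = [t for t in trials if t.status is TrialStatus.COMPLETED]
    if not completed:
        raise RuntimeError("no trial completed the budget")
    final_rungs = seen_rungs + ([budget] if budget > rungs[-1] else [])
    best = min(completed, key=lambda t: _sort_key(t, final_rungs))
    return best.config, trials


def total_epochs(trials: Sequence[HpoTrial]) -> int:
    """Exact epoch accounting over a finished search (resumed, not re-run)."""
    return int(sum(t.epochs_trained for t in trials))


def trials_frame(trials: Sequence[HpoTrial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        for rung, acc in sorted(t.metrics.items()):
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "rung": rung,
                    "epochs": t.epochs_trained,
                    "val_accuracy": acc,
                    "status": t.status.value,
                }
            )
        if not t.metrics:
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "rung": None,
                    "epochs": 0,
                    "val_accuracy": None,
                    "status": t.status.value,
                }
            )
    return pd.DataFrame(rows)


def panel_train_fn(data, split, model_spec: ModelSpec, *, seed: int = 0, pipeline=None):
    """Adapter training real models on a panel dataset for the search.

    The sampled ``activation``/``max_norm``/``dropout`` go into the model
    spec; the remaining keys populate the training configuration.  State is
    the live :class:`Trainer`, so promotion resumes rather than restarts.
    """

    def train_fn(config: dict, target_epoch: int, state):
        if state is None:
            spec = ModelSpec(
                backbone=model_spec.backbone,
                n_classes=model_spec.n_classes,
                n_readers=model_spec.n_readers,
                reader_emb_dim=model_spec.reader_emb_dim,
                activation=config.get("activation", model_spec.activation),
                max_norm=config.get("max_norm", model_spec.max_norm),
                dropout=float(config.get("dropout", model_spec.dropout)),
                use_reader_embeddings=model_spec.use_reader_embeddings,
                in_channels=model_spec.in_channels,
                toy_channels=model_spec.toy_channels,
            )
            target = (
                TrainTarget.READER_LABEL
                if spec.use_reader_embeddings
                else TrainTarget.FINAL_LABEL
            )
            cfg = make_train_config(config, seed=seed, target=target, epochs=target_epoch)
            from .model import build_model

            state = Trainer(build_model(spec, seed=seed), data, split, cfg, pipeline)
        state.run_epochs(target_epoch - state._epoch)
        return state.history[-1].val_accuracy, state

    return train_fn
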