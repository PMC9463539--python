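"""The reader-conditional radiograph classifier and its baseline.

Both variants share the same trunk: a convolutional backbone ends in a
feature map that global average pooling (GAP) turns into a D-dimensional
*image embedding*, followed by dropout and a linear 5-way softmax head.

The reader-embedding variant additionally maps a reader identifier through
an entity-embedding table (``n_readers x 32``), projects the embedding to
dimension D with an affine layer, applies an activation, and multiplies the
result *element-wise* into the image embedding before the head.  With an
identity activation, zero projection weights and unit projection bias the
modulation vector is all ones and the model reduces exactly to the
baseline; training starts near that point (table rows are initialized to
small Gaussian noise and the projection bias to 1).

The choice of activation controls whether readers can flip the sign of an
image feature's contribution: ReLU and sigmoid produce nonnegative
modulation, so the direction of association between a feature and a class
is shared across readers; identity and tanh allow per-reader sign flips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from enum import Enum

import numpy as np

from . import nn
from .labels import N_CLASSES

__all__ = [
    "BackboneKind",
    "ActivationKind",
    "ModelSpec",
    "ReaderNet",
    "build_model",
    "forward_reader",
    "forward_baseline",
    "apply_max_norm",
    "save_model",
    "load_model",
]


class BackboneKind(str, Enum):
    TOY_CNN = "TOY_CNN"
    RESNET18 = "RESNET18"
    RESNET34 = "RESNET34"
    RESNET50 = "RESNET50"


class ActivationKind(str, Enum):
    IDENTITY = "IDENTITY"
    RELU = "RELU"
    TANH = "TANH"
    SIGMOID = "SIGMOID"


_ACT_LAYERS = {
    ActivationKind.IDENTITY: nn.Identity,
    ActivationKind.RELU: nn.ReLU,
    ActivationKind.TANH: nn.Tanh,
    ActivationKind.SIGMOID: nn.Sigmoid,
}

#: Image-embedding dimension D fixed by the residual backbones.
_RESNET_DIMS = {
    BackboneKind.RESNET18: 512,
    BackboneKind.RESNET34: 512,
    BackboneKind.RESNET50: 2048,
}


@dataclass
class ModelSpec:
    """Architecture hyper-parameters for :func:`build_model`."""

    backbone: BackboneKind = BackboneKind.TOY_CNN
    n_classes: int = N_CLASSES
    n_readers: int = 1
    reader_emb_dim: int = 32
    activation: ActivationKind = ActivationKind.IDENTITY
    max_norm: float | None = None
    dropout: float = 0.0
    use_reader_embeddings: bool = True
    in_channels: int | None = None  # default: 1 for TOY_CNN, 3 for residual nets
    toy_channels: tuple[int, int, int] = (8, 16, 32)

    def __post_init__(self) -> None:
        self.backbone = BackboneKind(self.backbone)
        self.activation = ActivationKind(self.activation)
        if isinstance(self.toy_channels, list):
            self.toy_channels = tuple(self.toy_channels)
        if self.n_readers < 1:
            raise ValueError("n_readers must be >= 1")
        if self.reader_emb_dim < 1:
            raise ValueError("reader_emb_dim must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.max_norm is not None and self.max_norm <= 0:
            raise ValueError("max_norm must be positive")

    @property
    def embedding_dim(self) -> int:
        """The image-embedding dimension D."""
        if self.backbone is BackboneKind.TOY_CNN:
            return self.toy_channels[-1]
        return _RESNET_DIMS[self.backbone]

    @property
    def input_channels(self) -> int:
        if self.in_channels is not None:
            return self.in_channels
        return 1 if self.backbone is BackboneKind.TOY_CNN else 3


def _toy_backbone(spec: ModelSpec, rng: np.random.Generator) -> nn.Sequential:
    """Three strided conv-BN-ReLU blocks; cheap desk-scale workhorse.

    Each block halves the spatial resolution with a stride-2 convolution,
    so a 64x64 input ends in an 8x8 feature map before GAP.
    """
    layers: list[nn.Layer] = []
    in_ch = spec.input_channels
    for out_ch in spec.toy_channels:
        layers += [
            nn.Conv2d(in_ch, out_ch, 3, stride=2, pad=1, bias=False, rng=rng),
            nn.BatchNorm2d(out_ch),
            nn.ReLU(),
        ]
        in_ch = out_ch
    return nn.Sequential(layers)


def _basic_block(in_ch: int, out_ch: int, stride: int, rng: np.random.Generator) -> nn.ResidualBlock:
    main = nn.Sequential(
        [
            nn.Conv2d(in_ch, out_ch, 3, stride=stride, pad=1, bias=False, rng=rng),
            nn.BatchNorm2d(out_ch),
            nn.ReLU(),
            nn.Conv2d(out_ch, out_ch, 3, stride=1, pad=1, bias=False, rng=rng),
            nn.BatchNorm2d(out_ch),
        ]
    )
    shortcut = None
    if stride != 1 or in_ch != out_ch:
        shortcut = nn.Sequential(
            [nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng), nn.BatchNorm2d(out_ch)]
        )
    return nn.ResidualBlock(main, shortcut)


def _bottleneck_block(
    in_ch: int, mid_ch: int, stride: int, rng: np.random.Generator
) -> nn.ResidualBlock:
    out_ch = mid_ch * 4
    main = nn.Sequential(
        [
            nn.Conv2d(in_ch, mid_ch, 1, bias=False, rng=rng),
            nn.BatchNorm2d(mid_ch),
            nn.ReLU(),
            nn.Conv2d(mid_ch, mid_ch, 3, stride=stride, pad=1, bias=False, rng=rng),
            nn.BatchNorm2d(mid_ch),
            nn.ReLU(),
            nn.Conv2d(mid_ch, out_ch, 1, bias=False, rng=rng),
            nn.BatchNorm2d(out_ch),
        ]
    )
    shortcut = None
    if stride != 1 or in_ch != out_ch:
        shortcut = nn.Sequential(
            [nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng), nn.BatchNorm2d(out_ch)]
        )
    return nn.ResidualBlock(main, shortcut)


def _resnet_backbone(spec: ModelSpec, rng: np.random.Generator) -> nn.Sequential:
    """Residual backbone (18/34: basic blocks; 50: bottlenecks), random init."""
    cfg = {
        BackboneKind.RESNET18: ([2, 2, 2, 2], _basic_block, 1),
        BackboneKind.RESNET34: ([3, 4, 6, 3], _basic_block, 1),
        BackboneKind.RESNET50: ([3, 4, 6, 3], _bottleneck_block, 4),
    }[spec.backbone]
    n_blocks, block_fn, expansion = cfg
    layers: list[nn.Layer] = [
        nn.Conv2d(spec.input_channels, 64, 7, stride=2, pad=3, bias=False, rng=rng),
        nn.BatchNorm2d(64),
        nn.ReLU(),
        nn.MaxPool2d(3, stride=2, pad=1),
    ]
    in_ch = 64
    for stage, (width, n) in enumerate(zip((64, 128, 256, 512), n_blocks)):
        for b in range(n):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(block_fn(in_ch, width, stride, rng))
            in_ch = width * expansion
    return nn.Sequential(layers)


class ReaderNet:
    """Backbone -> GAP -> [reader modulation] -> dropout -> softmax head."""

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        root = np.random.SeedSequence(seed)
        init_ss, drop_ss = root.spawn(2)
        rng = np.random.default_rng(init_ss)
        if spec.backbone is BackboneKind.TOY_CNN:
            self.backbone = _toy_backbone(spec, rng)
        else:
            self.backbone = _resnet_backbone(spec, rng)
        D = spec.embedding_dim
        self.gap = nn.GlobalAvgPool()
        self.dropout = nn.Dropout(spec.dropout, rng=np.random.default_rng(drop_ss))
        self.head = nn.Linear(D, spec.n_classes, rng=rng, w_scale=np.sqrt(1.0 / D))
        if spec.use_reader_embeddings:
            self.embedding = nn.Embedding(spec.n_readers, spec.reader_emb_dim, rng=rng, scale=0.1)
            # small weights + unit bias start the modulation near 1 (baseline),
            # large enough that the two-layer branch escapes its saddle quickly
            self.projection = nn.Linear(
                spec.reader_emb_dim, D, rng=rng, w_scale=0.05, bias_init=1.0
            )
            self.emb_activation: nn.Layer = _ACT_LAYERS[spec.activation]()
        else:
            self.embedding = None
            self.projection = None
            self.emb_activation = None
        self.last_feature_map: np.ndarray | None = None
        self.last_modulation: np.ndarray | None = None

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1] != self.spec.input_channels:
            raise ValueError(
                f"expected input (B, {self.spec.input_channels}, H, W), got {x.shape}"
            )
        return x

    def modulation(self, reader_ids: np.ndarray, train: bool = False) -> np.ndarray:
        emb = self.embedding.forward(np.atleast_1d(reader_ids), train=train)
        return self.emb_activation.forward(self.projection.forward(emb, train=train), train=train)

    def forward(
        self,
        x: np.ndarray,
        reader_ids: np.ndarray | None = None,
        train: bool = False,
        capture: bool = False,
    ) -> np.ndarray:
        """Logits, shape (B, n_classes).  ``reader_ids=None`` = baseline path."""
        x = self._check_input(x)
        feat = self.backbone.forward(x, train=train)
        if capture:
            self.last_feature_map = feat
        h = self.gap.forward(feat, train=train)
        if reader_ids is not None:
            if not self.spec.use_reader_embeddings:
                raise ValueError("model was built without reader embeddings")
            m = self.modulation(np.asarray(reader_ids), train=train)
            if m.shape[0] != h.shape[0]:
                raise ValueError("reader_ids length must match batch size")
            if capture:
                self.last_modulation = m
            z = h * m
            self._mod_cache = (h, m) if train else None
        else:
            z = h
            self._mod_cache = None
            if capture:
                self.last_modulation = None
        z = self.dropout.forward(z, train=train)
        return self.head.forward(z, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.head.backward(dlogits)
        dz = self.dropout.backward(dz)
        if self._mod_cache is not None:
            h, m = self._mod_cache
            dh = dz * m
            dm = dz * h
            dproj = self.emb_activation.backward(dm)
            demb = self.projection.backward(dproj)
            self.embedding.backward(demb)
        else:
            dh = dz
        dfeat = self.gap.backward(dh)
        self.backbone.backward(dfeat)

    def predict_proba(
        self, x: np.ndarray, reader_ids: np.ndarray | None = None, capture: bool = False
    ) -> np.ndarray:
        return nn.softmax(self.forward(x, reader_ids, train=False, capture=capture))

    # -- parameter management ----------------------------------------------

    def param_groups(self) -> dict[str, list[nn.Layer]]:
        groups = {"conv": list(self.backbone.iter_layers()), "fc": [self.head]}
        if self.spec.use_reader_embeddings:
            groups["proj"] = [self.projection]
            groups["emb"] = [self.embedding]
        return groups

    def named_layers(self) -> list[tuple[str, nn.Layer]]:
        named = [(f"backbone.{i}", lay) for i, lay in enumerate(self.backbone.iter_layers())]
        named.append(("head", self.head))
        if self.spec.use_reader_embeddings:
            named += [("projection", self.projection), ("embedding", self.embedding)]
        return named

    def apply_max_norm(self) -> None:
        """Project embedding rows onto the L2 ball of radius ``spec.max_norm``."""
        if self.spec.use_reader_embeddings and self.spec.max_norm is not None:
            self.embedding.params["table"] = apply_max_norm(
                self.embedding.params["table"], self.spec.max_norm
            )

    def reader_branch_param_count(self) -> int:
        """Extra parameters added by the reader branch.

        Table (``n_readers x emb_dim``) plus the affine projection
        (``emb_dim x D`` weights and ``D`` biases).
        """
        s = self.spec
        if not s.use_reader_embeddings:
            return 0
        return s.n_readers * s.reader_emb_dim + s.reader_emb_dim * s.embedding_dim + s.embedding_dim

    def n_params(self) -> int:
        return sum(lay.n_params() for _, lay in self.named_layers())

    def summary(self) -> str:
        s = self.spec
        lines = [
            f"ReaderNet backbone={s.backbone.value} D={s.embedding_dim} "
            f"classes={s.n_classes} dropout={s.dropout}",
            f"reader embeddings: {'on' if s.use_reader_embeddings else 'off'}",
        ]
        if s.use_reader_embeddings:
            lines.append(
                f"  table {s.n_readers}x{s.reader_emb_dim}, projection "
                f"{s.reader_emb_dim}->{s.embedding_dim}, activation {s.activation.value}, "
                f"max_norm {s.max_norm}"
            )
            lines.append(f"  reader-branch parameters: {self.reader_branch_param_count()}")
        lines.append(f"total parameters: {self.n_params()}")
        return "\n".join(lines)


def build_model(spec: ModelSpec, seed: int = 0) -> ReaderNet:
    """Construct a model from its spec with seed-deterministic init."""
    return ReaderNet(spec, seed=seed)


def forward_baseline(model: ReaderNet, image_tensor: np.ndarray) -> np.ndarray:
    """Per-class probabilities ignoring reader identity (eval mode).

    A single image ``(C, H, W)`` yields a 5-vector; a batch yields ``(B, 5)``.
    """
    squeeze = np.asarray(image_tensor).ndim == 3
    probs = model.predict_proba(image_tensor, None)
    return probs[0] if squeeze else probs


def forward_reader(model: ReaderNet, image_tensor: np.ndarray, reader_id) -> np.ndarray:
    """Per-class probabilities conditional on a reader identity (eval mode)."""
    if not model.spec.use_reader_embeddings:
        raise ValueError("model was built without reader embeddings")
    x = np.asarray(image_tensor, dtype=np.float32)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    ids = np.asarray(reader_id)
    if ids.ndim == 0:
        ids = np.full(x.shape[0], int(ids), dtype=np.int64)
    probs = model.predict_proba(x, ids)
    return probs[0] if squeeze else probs


def apply_max_norm(table: np.ndarray, max_norm: float) -> np.ndarray:
    """Rescale rows whose L2 norm exceeds ``max_norm`` to lie on the ball."""
    if max_norm <= 0:
        raise ValueError("max_norm must be positive")
    table = np.asarray(table, dtype=np.float32)
    norms = np.linalg.norm(table, axis=1, keepdims=True)
    scale = np.where(norms > max_norm, max_norm / np.maximum(norms, 1e-12), 1.0)
    return (table * scale).astype(np.float32)


# -- checkpointing ----------------------------------------------------------

def save_model(model: ReaderNet, path) -> None:
    """Save spec, weights, BN running stats, and dropout rng state to one file."""
    arrays: dict[str, np.ndarray] = {}
    for name, layer in model.named_layers():
        for pname, p in layer.params.items():
            arrays[f"{name}.{pname}"] = p
        if isinstance(layer, nn.BatchNorm2d):
            arrays[f"{name}.running_mean"] = layer.running_mean
            arrays[f"{name}.running_var"] = layer.running_var
    spec_dict = asdict(model.spec)
    spec_dict["backbone"] = model.spec.backbone.value
    spec_dict["activation"] = model.spec.activation.value
    meta = {
        "spec": spec_dict,
        "seed": model.seed,
        "dropout_rng_state": model.dropout.rng.bit_generator.state,
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> ReaderNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec = ModelSpec(**{**meta["spec"], "toy_channels": tuple(meta["spec"]["toy_channels"])})
        model = ReaderNet(spec, seed=meta["seed"])
        for name, layer in model.named_layers():
            for pname in layer.params:
                layer.params[pname][...] = data[f"{name}.{pname}"]
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean[...] = data[f"{name}.running_mean"]
                layer.running_var[...] = data[f"{name}.running_var"]
        model.dropout.rng.bit_generator.state = meta["dropout_rng_state"]
    return model
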