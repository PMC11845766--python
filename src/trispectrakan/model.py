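"""TriSpectraKAN and the Hybrid-CNN baseline.

Both models share the three convolutional feature heads (MFCC 20x259,
chroma 12x259, mel-spectrogram 128x259 inputs, each mapped to a 256-dim
embedding) whose outputs are concatenated into a 768-dim fusion vector.
TriSpectraKAN classifies the fusion through a KAN [768, 769, 6]; the
baseline uses a dense stack 768 -> 750 -> 250 -> 75 -> 25 -> 6 with ReLU
and dropout between the hidden layers.

Each head: three conv blocks (32, 64, 256 filters, 3x3 kernels, batch
norm + ReLU, 2x2 max-pool after the first two blocks), global average
pooling, then a final batch norm — the same code path for all three input
heights.  The heads never share weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._nn import (BatchNorm, Conv2d, Dense, Dropout, GlobalAvgPool, MaxPool2,
                  Param, ReLU, Sequential, softmax)
from .kan import KANLayer, SplineSpec

__all__ = [
    "HeadConfig", "ModelConfig", "build_feature_head", "fuse_embeddings",
    "build_trispectrakan", "build_hybrid_cnn_baseline", "dense_param_count",
    "MultiHeadClassifier", "predict", "model_summary",
]

HEAD_ORDER = ("mfcc", "chroma", "mspec")
HEAD_HEIGHTS = {"mfcc": 20, "chroma": 12, "mspec": 128}


@dataclass(frozen=True)
class HeadConfig:
    """Geometry of one convolutional feature head."""

    input_height: int
    input_width: int = 259
    conv_filters: tuple[int, ...] = (32, 64, 256)
    embedding_dim: int = 256


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (final selected values)."""

    variant: str = "trispectrakan"
    n_classes: int = 6
    kan_hidden: int = 769
    spline: SplineSpec = field(default_factory=SplineSpec)
    mlp_widths: tuple[int, ...] = (750, 250, 75, 25)
    dropout_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.variant not in ("trispectrakan", "hybrid_cnn"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")


def dense_param_count(n_in: int, n_out: int) -> int:
    """Weights plus biases of one dense layer."""
    if n_in <= 0 or n_out <= 0:
        raise ValueError("widths must be positive")
    return n_in * n_out + n_out


def build_feature_head(cfg: HeadConfig, rng: np.random.Generator,
                       dtype=np.float32) -> Sequential:
    """Conv head mapping (N, height, 259, 1) -> (N, 256)."""
    f1, f2, f3 = cfg.conv_filters
    if f3 != cfg.embedding_dim:
        raise ValueError("last conv width must equal the embedding dim")
    conv1 = Conv2d(1, f1, rng, dtype=dtype)
    conv1.input_grad = False  # nothing upstream of the raw features
    return Sequential([
        conv1, BatchNorm(f1, dtype=dtype), ReLU(),
        MaxPool2(),
        Conv2d(f1, f2, rng, dtype=dtype), BatchNorm(f2, dtype=dtype), ReLU(),
        MaxPool2(),
        Conv2d(f2, f3, rng, dtype=dtype), BatchNorm(f3, dtype=dtype), ReLU(),
        GlobalAvgPool(),
        BatchNorm(cfg.embedding_dim, dtype=dtype),
    ])


def fuse_embeddings(e_mfcc: np.ndarray, e_chroma: np.ndarray,
                    e_mspec: np.ndarray) -> np.ndarray:
    """Concatenate the three 256-dim embeddings in fixed head order."""
    for e in (e_mfcc, e_chroma, e_mspec):
        if e.shape[-1] != 256:
            raise ValueError(f"expected 256-dim embeddings, got {e.shape}")
    return np.concatenate([e_mfcc, e_chroma, e_mspec], axis=-1)


class MultiHeadClassifier:
    """Three independent conv heads -> fused embedding -> classifier."""

    def __init__(self, heads: dict[str, Sequential], classifier: Sequential,
                 config: ModelConfig) -> None:
        self.heads = heads
        self.classifier = classifier
        self.config = config
        self._emb_dim = 256

    def params(self) -> list[Param]:
        out = []
        for name in HEAD_ORDER:
            out.extend(self.heads[name].params())
        out.extend(self.classifier.params())
        return out

    def param_count(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, inputs: list[np.ndarray], train: bool = False) -> np.ndarray:
        """``inputs`` = [mfcc, chroma, mspec] batches, each (N, h, W, 1)."""
        if len(inputs) != 3:
            raise ValueError("expected the three feature batches")
        embs = [self.heads[name].forward(x, train=train)
                for name, x in zip(HEAD_ORDER, inputs)]
        fused = fuse_embeddings(*embs)
        return self.classifier.forward(fused, train=train)

    def backward(self, grad_out: np.ndarray) -> None:
        g = self.classifier.backward(grad_out)
        d = self._emb_dim
        for i, name in enumerate(HEAD_ORDER):
            self.heads[name].backward(g[:, i * d:(i + 1) * d])

    def predict_proba(self, inputs: list[np.ndarray]) -> np.ndarray:
        return softmax(self.forward(inputs, train=False))


def _heads(rng: np.random.Generator, dtype) -> dict[str, Sequential]:
    return {name: build_feature_head(HeadConfig(HEAD_HEIGHTS[name]), rng,
                                     dtype=dtype)
            for name in HEAD_ORDER}


def build_trispectrakan(cfg: ModelConfig = ModelConfig(), seed: int = 0,
                        dtype=np.float32) -> MultiHeadClassifier:
    """Heads -> fusion -> batch norm -> KAN [768, 769, n_classes]."""
    if cfg.variant != "trispectrakan":
        raise ValueError("config variant must be 'trispectrakan'")
    rng = np.random.default_rng(seed)
    classifier = Sequential([
        BatchNorm(768, dtype=dtype),
        KANLayer(768, cfg.kan_hidden, cfg.spline, rng, dtype=dtype),
        KANLayer(cfg.kan_hidden, cfg.n_classes, cfg.spline, rng, dtype=dtype),
    ])
    return MultiHeadClassifier(_heads(rng, dtype), classifier, cfg)


def build_hybrid_cnn_baseline(cfg: ModelConfig = ModelConfig(variant="hybrid_cnn"),
                              seed: int = 0, dtype=np.float32) -> MultiHeadClassifier:
    """Heads -> fusion -> dense 768-750-250-75-25-n_classes with dropout."""
    if cfg.variant != "hybrid_cnn":
        raise ValueError("config variant must be 'hybrid_cnn'")
    rng = np.random.default_rng(seed)
    layers: list = []
    widths = (768,) + tuple(cfg.mlp_widths)
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        layers += [Dense(n_in, n_out, rng, dtype=dtype), ReLU(),
                   Dropout(cfg.dropout_rate, rng)]
    layers.append(Dense(widths[-1], cfg.n_classes, rng, dtype=dtype))
    return MultiHeadClassifier(_heads(rng, dtype), Sequential(layers), cfg)


def predict(model: MultiHeadClassifier, triple_inputs: list[np.ndarray]):
    """Class probabilities and argmax labels (ties -> lowest index).

    Accepts a batch of feature inputs; single segments should be passed
    with a leading batch axis of 1.
    """
    probs = model.predict_proba(triple_inputs)
    labels = probs.argmax(axis=-1)  # argmax returns the first maximum
    return probs, labels


def model_summary(model: MultiHeadClassifier) -> str:
    """Layer/parameter listing in the style of a model-specification table."""
    rows = [("mfcc input", "(20, 259, 1)", 0),
            ("chroma input", "(12, 259, 1)", 0),
            ("mspec input", "(128, 259, 1)", 0)]
    for name in HEAD_ORDER:
        n = sum(p.size for p in model.heads[name].params())
        rows.append((f"{name}Model", "(None, 256)", n))
    rows.append(("concatenate", "(None, 768)", 0))
    widths_in = 768
    for layer in model.classifier.layers:
        n = sum(p.size for p in layer.params())
        if isinstance(layer, KANLayer):
            rows.append(("KAN layer", f"(None, {layer.n_out})", n))
            widths_in = layer.n_out
        elif isinstance(layer, Dense):
            rows.append(("dense", f"(None, {layer.w.value.shape[1]})", n))
        elif n:
            rows.append((type(layer).__name__, f"(None, {widths_in})", n))
    total = model.param_count()
    lines = [f"{'Layer':<18}{'Output shape':<18}{'Param #':>12}"]
    lines += [f"{r[0]:<18}{r[1]:<18}{r[2]:>12,}" for r in rows]
    lines.append(f"{'Total params':<36}{total:>12,}")
    return "\n".join(lines)


def save_checkpoint(model: MultiHeadClassifier, path) -> None:
    """Flat binary checkpoint with a JSON header describing the variant."""
    cfg = model.config
    header = json.dumps({
        "variant": cfg.variant, "n_classes": cfg.n_classes,
        "kan_hidden": cfg.kan_hidden, "mlp_widths": list(cfg.mlp_widths),
        "dropout_rate": cfg.dropout_rate,
        "spline": [cfg.spline.order_k, cfg.spline.grid_size,
                   list(cfg.spline.grid_range)],
    })
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    bn_state = {}
    i = 0
    for seq in [model.heads[n] for n in HEAD_ORDER] + [model.classifier]:
        for layer in seq.layers:
            if isinstance(layer, BatchNorm):
                bn_state[f"bn{i}_mean"] = layer.running_mean
                bn_state[f"bn{i}_var"] = layer.running_var
                i += 1
    np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8),
             **arrays, **bn_state)


def load_checkpoint(path) -> MultiHeadClassifier:
    with np.load(path) as data:
        h = json.loads(bytes(data["header"]).decode())
        spline = SplineSpec(h["spline"][0], h["spline"][1], tuple(h["spline"][2]))
        cfg = ModelConfig(variant=h["variant"], n_classes=h["n_classes"],
                          kan_hidden=h["kan_hidden"],
                          mlp_widths=tuple(h["mlp_widths"]),
                          dropout_rate=h["dropout_rate"], spline=spline)
        model = (build_trispectrakan(cfg) if cfg.variant == "trispectrakan"
                 else build_hybrid_cnn_baseline(cfg))
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        i = 0
        for seq in [model.heads[n] for n in HEAD_ORDER] + [model.classifier]:
            for layer in seq.layers:
                if isinstance(layer, BatchNorm):
                    layer.running_mean[...] = data[f"bn{i}_mean"]
                    layer.running_var[...] = data[f"bn{i}_var"]
                    i += 1
    return model
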