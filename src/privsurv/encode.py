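"""First-layer modality-specific encoders producing fixed-length representations.

Each genomic modality (mRNA, miRNA, CNV) is encoded by a stack of 2-4 fully
connected layers with batch normalisation and ReLU, followed by a linear
projection to the shared representation length ``d``. The clinical branch
embeds the four categorical fields, applies dropout to the embedded vectors,
concatenates the normalised continuous values (age) and maps through one
affine + ReLU layer to width ``d``. The per-patient representations of the
four modalities are stacked into the representation tensor ``B`` of shape
``(patients, modalities, d)`` — the modality-token matrix consumed by the
attention fusion layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .synthetic import MODALITY_ORDER

__all__ = [
    "EncoderConfig",
    "RepresentationBundle",
    "GenomicEncoder",
    "ClinicalEncoder",
    "build_encoder",
    "stack_representations",
]

GENOMIC_MODALITIES = ("mRNA", "miRNA", "CNV")


@dataclass(frozen=True)
class EncoderConfig:
    modality: str
    n_features: int = 0                      # input width (genomic) — set from data
    hidden_widths: tuple = (512, 128)        # 2-4 FC layers for genomic modalities
    rep_length: int = 128                    # d
    dropout_rate: float = 0.1
    use_batchnorm: bool = True
    embedding_dims: dict = field(default_factory=dict)   # clinical only

    def validate(self) -> None:
        if self.rep_length <= 0:
            raise ValueError("rep_length must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.modality in GENOMIC_MODALITIES:
            if not 2 <= len(self.hidden_widths) <= 4:
                raise ValueError(
                    f"{self.modality}: encoder depth must be 2-4 FC layers, "
                    f"got widths {list(self.hidden_widths)}")
            if any(w <= 0 for w in self.hidden_widths):
                raise ValueError("all hidden widths must be positive")


@dataclass
class RepresentationBundle:
    """Per-sample stack of modality representations (the matrix ``B``)."""

    B: np.ndarray                       # patients x modalities x d
    modality_order: tuple = MODALITY_ORDER

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 3:
            raise ValueError("B must be patients x modalities x d")
        if not np.all(np.isfinite(self.B)):
            raise ValueError("representation bundle contains non-finite entries")

    @property
    def d(self) -> int:
        return self.B.shape[2]


class GenomicEncoder:
    """2-4 FC layers (+ BN + ReLU) and a linear projection to width d."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        config.validate()
        if config.n_features <= 0:
            raise ValueError(f"{config.modality}: n_features must be set")
        self.config = config
        layers: list = []
        width = config.n_features
        for w in config.hidden_widths:
            layers.append(nn.Dense(width, w, rng))
            if config.use_batchnorm:
                layers.append(nn.BatchNorm(w))
            layers.append(nn.ReLU())
            width = w
        layers.append(nn.Dense(width, config.rep_length, rng))
        self.net = nn.MLP(layers)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite encoder input")
        return self.net.forward(x, training=training, rng=rng)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.net.backward(g)

    def params(self) -> dict[str, nn.Param]:
        return self.net.params()

    def set_frozen_batchnorm(self, frozen: bool) -> None:
        self.net.set_frozen_batchnorm(frozen)

    # Layers that carry per-sample gradient factors (Dense, BatchNorm).
    def affine_layers(self) -> list:
        return [(f"layer{i}", l) for i, l in enumerate(self.net.layers)
                if hasattr(l, "per_sample_l1")]


class ClinicalEncoder:
    """Categorical embeddings + dropout, concat age, one affine + ReLU to d."""

    def __init__(self, config: EncoderConfig, n_levels: dict[str, int],
                 n_continuous: int, rng: np.random.Generator):
        config.validate()
        if not config.embedding_dims:
            raise ValueError("clinical encoder needs embedding_dims")
        self.config = config
        self.fields = list(config.embedding_dims)
        self.embeddings = {f: nn.Embedding(n_levels[f], dim, rng)
                           for f, dim in config.embedding_dims.items()}
        self.dropout = nn.Dropout(config.dropout_rate)
        emb_width = sum(config.embedding_dims.values())
        self.proj = nn.Dense(emb_width + n_continuous, config.rep_length, rng)
        self.act = nn.ReLU()
        self._splits: list[int] = list(np.cumsum(
            [config.embedding_dims[f] for f in self.fields]))[:-1]
        self._emb_width = emb_width

    def forward(self, cat_idx: np.ndarray, cont: np.ndarray,
                training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        embedded = np.concatenate(
            [self.embeddings[f].forward(cat_idx[:, j], training=training, rng=rng)
             for j, f in enumerate(self.fields)], axis=1)
        embedded = self.dropout.forward(embedded, training=training, rng=rng)
        h = np.concatenate([embedded, cont], axis=1)
        return self.act.forward(self.proj.forward(h, training=training, rng=rng))

    def backward(self, g: np.ndarray) -> None:
        g = self.proj.backward(self.act.backward(g))
        g_emb = self.dropout.backward(g[:, :self._emb_width])
        for f, part in zip(self.fields, np.split(g_emb, self._splits, axis=1)):
            self.embeddings[f].backward(part)

    def params(self) -> dict[str, nn.Param]:
        out = {f"emb_{f}.table": e.table for f, e in self.embeddings.items()}
        out.update({f"proj.{k}": p for k, p in self.proj.params().items()})
        return out


def build_encoder(config: EncoderConfig, rng: np.random.Generator,
                  n_levels: dict[str, int] | None = None,
                  n_continuous: int = 1):
    """Construct the encoder for one modality from a seeded generator."""
    if config.modality == "clinical":
        return ClinicalEncoder(config, n_levels or {}, n_continuous, rng)
    if config.modality in GENOMIC_MODALITIES:
        return GenomicEncoder(config, rng)
    raise ValueError(f"unknown modality {config.modality!r}")


def stack_representations(reps: dict[str, np.ndarray],
                          modality_order: tuple = MODALITY_ORDER
                          ) -> RepresentationBundle:
    """Stack per-modality (patients x d) outputs into ``B`` in fixed order."""
    widths = {m: r.shape[1] for m, r in reps.items()}
    if len(set(widths.values())) != 1:
        raise ValueError(f"representation width mismatch across modalities: {widths}")
    missing = [m for m in modality_order if m not in reps]
    if missing:
        raise ValueError(f"missing representations for modalities {missing}")
    B = np.stack([reps[m] for m in modality_order], axis=1)
    return RepresentationBundle(B=B, modality_order=tuple(modality_order))
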