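"""Second-layer multihead-attention fusion over modality tokens.

Per patient, the four modality representations form a token matrix
``B_tokens`` of shape ``(tokens, d)``. Keys are ``relu(dropout(B W))`` with a
trainable ``d x d`` matrix ``W`` (standard-Gaussian init); values are the
untransformed tokens (identity); the query is a single learnable length-``d``
vector shared across patients. Query, keys and values are split into ``H``
blocks of width ``d/H``; each head computes scaled dot-product attention over
the tokens (scale ``1/sqrt(d/H)``, the transformer convention), the head
outputs are concatenated, and a final elementwise projection by ``w_last``
yields the fused feature ``Y``. Dropout layers are disabled in evaluation
mode, making the eval forward pass deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .encode import RepresentationBundle

__all__ = [
    "FusionParams",
    "AttentionOutput",
    "MultiheadFusion",
    "project_keys",
    "split_heads",
    "attention_head",
    "multihead_fuse",
    "softmax",
]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class FusionParams:
    """Trainable fusion parameters, reproducibly initialised from a seed.

    ``W`` is standard Gaussian; ``q`` is uniform on ``(-1/sqrt(d), 1/sqrt(d))``
    (the uniform bound is a package choice; only the distribution family is
    prescribed). ``w_last`` starts at ones — an identity gate, so the fused
    feature initially passes the attention output through unchanged, which
    keeps early gradients to the encoders well-scaled.
    """

    d: int
    H: int
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.d % self.H != 0:
            raise ValueError(f"head count H={self.H} must divide d={self.d}")
        rng = np.random.default_rng(self.seed)
        bound = 1.0 / np.sqrt(self.d)
        self.W = rng.standard_normal((self.d, self.d))
        self.q = rng.uniform(-bound, bound, size=self.d)
        self.w_last = np.ones(self.d)


@dataclass
class AttentionOutput:
    Y: np.ndarray         # patients x d (fused feature per patient)
    weights: np.ndarray   # patients x H x tokens; each head row sums to 1


def project_keys(B_tokens: np.ndarray, W: np.ndarray,
                 dropout_rate: float = 0.0, mode: str = "eval",
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """``K = relu(dropout(B_tokens W))``; dropout is identity in eval mode."""
    if not np.all(np.isfinite(B_tokens)):
        raise ValueError("non-finite token input")
    pre = B_tokens @ W
    if mode == "train" and dropout_rate > 0.0:
        if rng is None:
            raise ValueError("train-mode key projection requires an rng")
        keep = 1.0 - dropout_rate
        pre = pre * ((rng.random(pre.shape) < keep) / keep)
    return np.maximum(pre, 0.0)


def split_heads(x: np.ndarray, H: int) -> list[np.ndarray]:
    """Split the embedding (last) dimension into ``H`` blocks of width d/H."""
    d = x.shape[-1]
    if d % H != 0:
        raise ValueError(f"H={H} does not divide d={d}")
    return np.split(x, H, axis=-1)


def attention_head(q_h: np.ndarray, K_h: np.ndarray,
                   V_h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention of one head over the tokens.

    ``weights = softmax(K_h q_h / sqrt(d_h))`` over the token axis; the output
    is the weight-averaged sum of the value rows.
    """
    dh = q_h.shape[-1]
    scores = (K_h @ q_h) / np.sqrt(dh)
    weights = softmax(scores, axis=-1)
    out = np.einsum("...t,...tk->...k", weights, V_h)
    return out, weights


class MultiheadFusion:
    """Trainable batched fusion layer with explicit backward pass."""

    def __init__(self, params: FusionParams):
        self.config = params
        self.W = nn.Param(params.W)
        self.q = nn.Param(params.q)
        self.w_last = nn.Param(params.w_last)
        self.d, self.H = params.d, params.H
        self.dh = self.d // self.H
        self.dropout_rate = params.dropout_rate
        self._cache: dict = {}

    def forward(self, bundle: RepresentationBundle, training: bool = False,
                rng: np.random.Generator | None = None) -> AttentionOutput:
        B = bundle.B                              # (n, T, d)
        if B.shape[2] != self.d:
            raise ValueError(f"bundle width {B.shape[2]} != fusion d {self.d}")
        n, T, d = B.shape
        H, dh = self.H, self.dh

        pre = B @ self.W.data
        if training and self.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("training-mode fusion requires an rng")
            keep = 1.0 - self.dropout_rate
            mask1 = (rng.random(pre.shape) < keep) / keep
        else:
            mask1 = 1.0
        D = pre * mask1
        K = np.maximum(D, 0.0)

        # Each head is the generic attention_head applied to its d/H block,
        # with V the untransformed token block (identity values).
        weights = np.empty((n, H, T))
        M = np.empty((n, d))
        for h in range(H):
            sl = slice(h * dh, (h + 1) * dh)
            out_h, a_h = attention_head(self.q.data[sl], K[:, :, sl], B[:, :, sl])
            weights[:, h, :] = a_h
            M[:, sl] = out_h

        if training and self.dropout_rate > 0.0:
            keep = 1.0 - self.dropout_rate
            mask2 = (rng.random(M.shape) < keep) / keep
        else:
            mask2 = 1.0
        Mdrop = M * mask2
        Y = Mdrop * self.w_last.data

        self._cache = {"B": B, "D": D, "K": K, "weights": weights,
                       "M": M, "Mdrop": Mdrop, "mask1": mask1, "mask2": mask2}
        return AttentionOutput(Y=Y, weights=weights)

    def backward(self, gY: np.ndarray) -> np.ndarray:
        """Gradient wrt the token bundle; accumulates parameter gradients."""
        c = self._cache
        B, D, K, a = c["B"], c["D"], c["K"], c["weights"]
        n, T, d = B.shape
        H, dh = self.H, self.dh
        scale = 1.0 / np.sqrt(dh)

        self.w_last.grad += (c["Mdrop"] * gY).sum(axis=0)
        gM = gY * self.w_last.data * c["mask2"]

        gK = np.zeros_like(K)
        gB = np.zeros_like(B)
        for h in range(H):
            sl = slice(h * dh, (h + 1) * dh)
            gMh = gM[:, sl]                                    # (n, dh)
            ah = a[:, h, :]                                    # (n, T)
            gB[:, :, sl] += ah[:, :, None] * gMh[:, None, :]
            ga = np.einsum("nk,ntk->nt", gMh, B[:, :, sl])
            gs = ah * (ga - (ah * ga).sum(axis=1, keepdims=True))
            self.q.grad[sl] += scale * np.einsum("nt,ntk->k", gs, K[:, :, sl])
            gK[:, :, sl] += scale * gs[:, :, None] * self.q.data[None, None, sl]

        gD = gK * (D > 0) * c["mask1"]
        self.W.grad += np.einsum("ntd,nte->de", B, gD)
        gB += gD @ self.W.data.T
        return gB

    def params(self) -> dict[str, nn.Param]:
        return {"W": self.W, "q": self.q, "w_last": self.w_last}


def multihead_fuse(bundle: RepresentationBundle, params: FusionParams,
                   mode: str = "eval",
                   rng: np.random.Generator | None = None) -> AttentionOutput:
    """Functional fusion forward pass (no gradient bookkeeping kept)."""
    layer = MultiheadFusion(params)
    return layer.forward(bundle, training=(mode == "train"), rng=rng)


def attention_weights_frame(output: AttentionOutput, patient_ids: list,
                            modality_order: tuple):
    """Tidy per-patient attention table (patient_id, head, modality, weight)."""
    import pandas as pd
    n, H, T = output.weights.shape
    rows = [{"patient_id": patient_ids[i], "head": h,
             "modality": modality_order[t],
             "weight": float(output.weights[i, h, t])}
            for i in range(n) for h in range(H) for t in range(T)]
    return pd.DataFrame(rows)
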