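"""Layer-wise relevance propagation (LRP) from the survival output to inputs.

Relevance is redistributed backward through the network with the
epsilon-rule: the relevance of an upper neuron ``q`` is split over its inputs
``e`` proportionally to the affine messages ``z_eq = v_e w_eq + u_q / fan_in``
(the bias is apportioned equally among contributing neurons), with a small
sign-matched stabilizer added to the denominator to bound the quotients.
Because the messages of a layer sum to its pre-activations, relevance is
conserved layer to layer up to the bias apportioning and the stabilizer.

The propagation path: the survival head's relevance is initialised to its
pre-activation outputs (summed over outputs during the backward sweep), passed
through the elementwise final projection, distributed over modality tokens
proportionally to their attention-weighted value contributions (the attention
weights are held constant — the key/query computation graph is not
decomposed), and then propagated through each genomic encoder down to its
input features. Per-feature scores are the mean absolute per-patient
relevance over the reference batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .encode import GENOMIC_MODALITIES

__all__ = [
    "RelevanceMap",
    "PercentileSummary",
    "affine_message",
    "lrp_backward_layer",
    "lrp_backward_diagonal",
    "distribute_over_tokens",
    "feature_relevance",
    "percentile_summary",
    "PERCENTILES",
]

PERCENTILES = (25, 50, 75, 100)
DEFAULT_STABILIZER = 1e-6


def _signed(x: np.ndarray, stabilizer: float) -> np.ndarray:
    """Add a sign-matched stabilizer (sign(0) treated as +)."""
    s = np.where(x >= 0, 1.0, -1.0)
    return x + s * stabilizer


def affine_message(v_e: float, w_eq: float, u_q: float, fan_in: int) -> float:
    """Message neuron ``e`` sends to ``q``: its affine share of ``R_q``."""
    return v_e * w_eq + u_q / fan_in


def lrp_backward_layer(upper_relevance: np.ndarray, activations: np.ndarray,
                       weights: np.ndarray, biases: np.ndarray,
                       stabilizer: float = DEFAULT_STABILIZER) -> np.ndarray:
    """Propagate relevance through one dense layer with the epsilon-rule.

    ``R_e = sum_q R_q z_eq / (sum_e' z_e'q + sign * stabilizer)`` where
    ``z_eq = v_e w_eq + u_q / fan_in``. The denominator equals the layer's
    pre-activation, so the 3-dimensional message tensor is never materialised.
    """
    if not (np.all(np.isfinite(upper_relevance)) and np.all(np.isfinite(activations))):
        raise ValueError("non-finite input to LRP layer")
    fan_in = activations.shape[1]
    denom = _signed(activations @ weights + biases, stabilizer)
    s = upper_relevance / denom                                  # (n, q)
    lower = activations * (s @ weights.T)
    lower += (s @ (biases / fan_in))[:, None]
    if not np.all(np.isfinite(lower)):
        raise ValueError("non-finite relevance produced; increase the stabilizer")
    return lower


def lrp_backward_diagonal(upper_relevance: np.ndarray, activations: np.ndarray,
                          scale: np.ndarray, shift: np.ndarray,
                          stabilizer: float = DEFAULT_STABILIZER) -> np.ndarray:
    """Epsilon-rule through a per-coordinate affine map (batchnorm, gating)."""
    z = activations * scale + shift
    return upper_relevance * z / _signed(z, stabilizer)


def distribute_over_tokens(upper_relevance: np.ndarray, weights: np.ndarray,
                           tokens: np.ndarray,
                           stabilizer: float = DEFAULT_STABILIZER) -> np.ndarray:
    """Split fused-feature relevance over modality tokens.

    The fused coordinate ``M_k = sum_t a_t V_tk`` is linear in the values;
    each token receives the share of its attention-weighted contribution.

    Parameters: ``upper_relevance (n, d)``, per-coordinate attention weights
    ``weights (n, T, d)`` (head weights broadcast over their d/H block),
    ``tokens (n, T, d)``. Returns ``(n, T, d)``.
    """
    z = weights * tokens                                  # (n, T, d)
    denom = _signed(z.sum(axis=1), stabilizer)            # (n, d)
    return upper_relevance[:, None, :] * z / denom[:, None, :]


@dataclass
class RelevanceMap:
    """Per-layer and per-input-feature relevance for the genomic modalities."""

    layers: dict                 # modality -> list of (layer_name, (n, width) matrix)
    feature_scores: dict         # modality -> per-feature score (mean |R|)
    output_relevance: np.ndarray
    stabilizer: float = DEFAULT_STABILIZER

    def __post_init__(self):
        if self.stabilizer <= 0:
            raise ValueError("stabilizer must be positive")

    def to_frame(self, feature_names: dict | None = None) -> pd.DataFrame:
        """Tidy per-feature table (modality, feature_name, score)."""
        rows = []
        for m, scores in self.feature_scores.items():
            names = (feature_names or {}).get(
                m, [f"{m}_f{j}" for j in range(len(scores))])
            rows.extend({"modality": m, "feature_name": n, "score": float(s)}
                        for n, s in zip(names, scores))
        return pd.DataFrame(rows)


@dataclass
class PercentileSummary:
    """Relevance scores at the 25/50/75/100th percentiles per layer."""

    table: pd.DataFrame          # columns: modality, layer, percentile, score

    def __post_init__(self):
        for (_, _), grp in self.table.groupby(["modality", "layer"]):
            vals = grp.sort_values("percentile")["score"].to_numpy()
            if np.any(np.diff(vals) < 0):
                raise ValueError("percentile scores must be nondecreasing")


def _nearest_rank(sorted_ascending: np.ndarray, pct: int) -> float:
    n = len(sorted_ascending)
    if n == 0:
        raise ValueError("empty score set")
    rank = max(1, int(np.ceil(pct / 100.0 * n)))
    return float(sorted_ascending[rank - 1])


def encoder_relevance(encoder, rep_relevance: np.ndarray,
                      stabilizer: float = DEFAULT_STABILIZER
                      ) -> list[tuple[str, np.ndarray]]:
    """Propagate relevance from a genomic encoder's representation to its input.

    Returns ``[(layer_name, relevance matrix), ...]`` ordered from the
    representation ("output") down to the input features ("input"). Requires a
    preceding eval-mode forward pass (cached activations).
    """
    layers = encoder.net.layers
    if getattr(layers[-1], "_x", None) is None:
        raise RuntimeError("encoder has no cached activations; run an eval forward pass first")
    out: list[tuple[str, np.ndarray]] = [("output", rep_relevance)]
    R = rep_relevance
    n_dense = sum(isinstance(l, nn.Dense) for l in layers)
    dense_idx = n_dense
    for layer in reversed(layers):
        if isinstance(layer, nn.Dense):
            R = lrp_backward_layer(R, layer._x, layer.W.data, layer.b.data,
                                   stabilizer)
            dense_idx -= 1
            name = "input" if dense_idx == 0 else f"layer{dense_idx}"
            out.append((name, R))
        elif isinstance(layer, nn.BatchNorm):
            scale, shift = layer.affine_view()
            x = (layer._xhat / layer._istd) + layer.running_mean
            R = lrp_backward_diagonal(R, x, scale, shift, stabilizer)
        # ReLU / Dropout: relevance passes through unchanged (the activation
        # is treated as part of the neuron, dropout is identity in eval mode).
    return out


def feature_relevance(model, batch, stabilizer: float = DEFAULT_STABILIZER
                      ) -> RelevanceMap:
    """Score every genomic input feature's association with the survival output.

    ``model`` is a :class:`privsurv.survival.SurvivalModel`; ``batch`` is a
    dataset slice accepted by its forward pass. One eval-mode forward pass is
    run to populate the activation caches, relevance is initialised at the
    head's pre-activation outputs, and the epsilon-rule is applied down to the
    input features of each genomic encoder.
    """
    if stabilizer <= 0:
        raise ValueError("stabilizer must be positive")
    out = model.forward(batch, training=False)
    head = model.head
    z = out["logits"]                                     # head pre-activations
    R_out = z.copy()

    # head dense: relevance onto the fused feature Y (sums over outputs).
    R_Y = lrp_backward_layer(R_out, head._x, head.W.data, head.b.data, stabilizer)

    # elementwise final projection Y = M * w_last (shift 0).
    M = model.fusion._cache["M"]
    R_M = lrp_backward_diagonal(R_Y, M, model.fusion.w_last.data,
                                np.zeros_like(model.fusion.w_last.data), stabilizer)

    # attention mixing: broadcast each head's token weights over its block.
    B = model.fusion._cache["B"]
    w = model.fusion._cache["weights"]                    # (n, H, T)
    n, T, d = B.shape
    dh = model.fusion.dh
    per_coord = np.repeat(np.transpose(w, (0, 2, 1)), dh, axis=2)   # (n, T, d)
    R_tokens = distribute_over_tokens(R_M, per_coord, B, stabilizer)

    layers: dict = {}
    scores: dict = {}
    for m in GENOMIC_MODALITIES:
        if m not in model.genomic_encoders:
            continue
        tok = model.modality_order.index(m)
        trace = encoder_relevance(model.genomic_encoders[m],
                                  R_tokens[:, tok, :], stabilizer)
        layers[m] = trace
        scores[m] = np.abs(trace[-1][1]).mean(axis=0)
    return RelevanceMap(layers=layers, feature_scores=scores,
                        output_relevance=R_out, stabilizer=stabilizer)


def percentile_summary(rmap: RelevanceMap) -> PercentileSummary:
    """Nearest-rank 25/50/75/100th percentile of each layer's score spectrum.

    Scores are the mean absolute relevance per neuron over the reference
    batch, matching the per-feature aggregation.
    """
    rows = []
    for m, trace in rmap.layers.items():
        for layer_name, R in trace:
            if R.size == 0:
                raise ValueError(f"empty relevance layer {layer_name!r} in {m!r}")
            neuron_scores = np.sort(np.abs(R).mean(axis=0))
            for pct in PERCENTILES:
                rows.append({"modality": m, "layer": layer_name,
                             "percentile": pct,
                             "score": _nearest_rank(neuron_scores, pct)})
    return PercentileSummary(table=pd.DataFrame(rows))
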