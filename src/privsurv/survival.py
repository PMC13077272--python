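"""End-to-end survival model: assembly, losses, training, prediction.

The model encodes each modality to a length-``d`` representation, fuses the
four modality tokens with multihead attention, and maps the fused feature to a
survival head. The default head is a discrete-time likelihood over
equal-quantile time bins (per-bin conditional hazards through a sigmoid); a
Cox partial-likelihood head (Breslow ties) is available as an option. Risk is
summarised as one minus the mean predicted survival over bins — any strictly
monotone functional gives the same concordance ordering; this one is fixed
for determinism.

Training follows the reference settings: Adam, learning rate 0.001, batch
size 256, 100 epochs (all configurable). With privacy enabled, input-feature
relevance is refreshed every ``refresh_epochs`` epochs on a fixed reference
batch, budgets are re-allocated, and every step the genomic encoders'
per-sample gradients are clipped (L1 bound ``C``) and perturbed with
group-wise Laplace noise before the optimizer update; batch normalisation in
the protected encoders runs on running statistics during private steps so
gradients stay per-sample separable. The clinical branch, fusion layer and
head are updated noiselessly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .encode import (GENOMIC_MODALITIES, EncoderConfig, build_encoder,
                     stack_representations)
from .fuse import FusionParams, MultiheadFusion
from .preprocess import (ClinicalVocabulary, FeatureStats, PreprocessConfig,
                         encode_clinical, impute_missing, minmax_normalize,
                         variance_filter)
from .privacy import (AllocationConfig, BudgetAllocation, PrivacyLedger,
                      allocate_budgets, laplace_sample)
from .relevance import DEFAULT_STABILIZER, feature_relevance
from .synthetic import MODALITY_ORDER, ModalityBlock, SurvivalRecord, records_to_arrays

__all__ = [
    "ModelConfig",
    "Dataset",
    "PreprocessArtifacts",
    "prepare_dataset",
    "SurvivalModel",
    "TrainedModel",
    "survival_loss",
    "discrete_time_nll",
    "cox_partial_likelihood",
    "predict_risk",
    "train",
    "StatusClassifier",
    "classify_status",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; defaults follow the reference training settings."""

    hidden_widths: dict = field(default_factory=lambda: {
        "mRNA": (512, 128), "miRNA": (256, 128), "CNV": (512, 128)})
    rep_length: int = 128
    heads: int = 8
    dropout_rate: float = 0.1
    use_batchnorm: bool = True
    head: str = "discrete_time"          # or "cox"
    time_bins: int = 20
    optimizer: str = "adam"              # or "sgd"
    learning_rate: float = 0.001
    batch_size: int = 256
    epochs: int = 100
    weight_decay: float = 1e-5
    privacy: bool = False
    clip_bound: float = 1.0
    refresh_epochs: int = 5
    stabilizer: float = DEFAULT_STABILIZER
    allocation: AllocationConfig = field(default_factory=AllocationConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.head not in ("discrete_time", "cox"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.time_bins <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("time_bins, batch_size and epochs must be positive")
        if self.clip_bound <= 0:
            raise ValueError("clip bound must be positive")


@dataclass
class Dataset:
    """Preprocessed, model-ready arrays for one cohort (or split)."""

    cat: np.ndarray                  # (n, n_categorical) int indices
    cont: np.ndarray                 # (n, n_continuous) in [0, 1]
    genomic: dict                    # modality -> (n, p) float
    times: np.ndarray
    events: np.ndarray
    patient_ids: list

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def status_labels(self) -> np.ndarray:
        return self.events.astype(int)

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(cat=self.cat[idx], cont=self.cont[idx],
                       genomic={m: v[idx] for m, v in self.genomic.items()},
                       times=self.times[idx], events=self.events[idx],
                       patient_ids=[self.patient_ids[i] for i in idx])


@dataclass
class PreprocessArtifacts:
    """Frozen preprocessing state, reused at inference / external validation."""

    vocab: ClinicalVocabulary
    genomic_stats: dict              # modality -> FeatureStats (post-filter)
    feature_names: dict              # modality -> kept feature names


def prepare_dataset(blocks: list[ModalityBlock], records: list[SurvivalRecord],
                    artifacts: PreprocessArtifacts | None = None,
                    variance_thresholds: dict | None = None,
                    config: PreprocessConfig | None = None
                    ) -> tuple[Dataset, PreprocessArtifacts]:
    """Run the full preprocessing pipeline and return model-ready arrays.

    When ``artifacts`` is given (inference on new data), its vocabulary,
    feature lists and normalisation statistics are applied frozen; otherwise
    they are fitted on this cohort. ``variance_thresholds`` defaults to no
    screening — pass :data:`privsurv.preprocess.DEFAULT_VARIANCE_THRESHOLDS`
    for the mRNA=7 / CNV=0.2 convention used with expression-scale data.
    """
    config = config or PreprocessConfig(variance_threshold=variance_thresholds or {})
    by_name = {b.name: b for b in blocks}
    times, events = records_to_arrays(records)

    clin = impute_missing(by_name["clinical"])
    if artifacts is None:
        vocab = ClinicalVocabulary.fit(clin, config)
        genomic_stats, feature_names = {}, {}
    else:
        vocab = artifacts.vocab
    cat, cont = encode_clinical(clin, vocab, config)

    genomic = {}
    for m in GENOMIC_MODALITIES:
        if m not in by_name:
            continue
        block = impute_missing(by_name[m])
        if artifacts is None:
            thr = (variance_thresholds or {}).get(m)
            if thr is not None:
                block = variance_filter(block, thr)
            stats = FeatureStats.fit(block)
            genomic_stats[m] = stats
            feature_names[m] = list(block.feature_names)
        else:
            from .preprocess import align_external_features
            block = align_external_features(block, artifacts.feature_names[m])
            stats = artifacts.genomic_stats[m]
        block = minmax_normalize(block, stats)
        genomic[m] = block.values

    if artifacts is None:
        artifacts = PreprocessArtifacts(vocab=vocab, genomic_stats=genomic_stats,
                                        feature_names=feature_names)
    ds = Dataset(cat=cat, cont=cont, genomic=genomic, times=times,
                 events=events, patient_ids=[r.patient_id for r in records])
    return ds, artifacts


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

_EPS = 1e-7


def discrete_time_nll(logits: np.ndarray, bin_idx: np.ndarray,
                      events: np.ndarray) -> tuple[float, np.ndarray]:
    """Right-censored discrete-time negative log-likelihood (summed).

    An event in bin ``k`` contributes its hazard at ``k`` and survival through
    the earlier bins; a censored record contributes survival through its bin.
    Returns the sum over samples and the gradient wrt the logits.
    """
    n, T = logits.shape
    h = 1.0 / (1.0 + np.exp(-logits))
    cols = np.arange(T)[None, :]
    at_risk = cols <= bin_idx[:, None]
    target = (cols == bin_idx[:, None]) & (events[:, None] == 1)
    hc = np.clip(h, _EPS, 1.0 - _EPS)
    ll = np.where(target, np.log(hc), np.log1p(-hc)) * at_risk
    loss = -float(ll.sum())
    grad = (h - target) * at_risk
    return loss, grad


def cox_partial_likelihood(scores: np.ndarray, times: np.ndarray,
                           events: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative Cox partial log-likelihood with Breslow tie handling (summed)."""
    if np.any(times <= 0):
        raise ValueError("nonpositive survival times")
    s = scores.ravel()
    order = np.argsort(-times, kind="stable")        # decreasing time
    s_ord = s[order]
    e_ord = events[order]
    t_ord = times[order]
    smax = s_ord.max()
    exp_s = np.exp(s_ord - smax)
    cum = np.cumsum(exp_s)
    # Breslow: the risk set of an event at time t is everyone with t_j >= t,
    # including all records tied at t. Group samples by tied time.
    n = len(s_ord)
    starts: list[int] = []
    i = 0
    while i < n:
        starts.append(i)
        j = i
        while j < n and t_ord[j] == t_ord[i]:
            j += 1
        i = j
    starts.append(n)

    loss = 0.0
    group_term = np.zeros(len(starts) - 1)           # n_events / risk-denominator
    for g in range(len(starts) - 1):
        i, j = starts[g], starts[g + 1]
        denom = cum[j - 1]
        n_events = int(e_ord[i:j].sum())
        if n_events:
            loss -= float(s_ord[i:j][e_ord[i:j] == 1].sum() - smax * n_events)
            loss += n_events * float(np.log(denom))
            group_term[g] = n_events / denom
    # sample j sits in the risk sets of events at equal or smaller times,
    # i.e. of its own group and every later group in decreasing-time order
    suffix = np.cumsum(group_term[::-1])[::-1]
    grad_ord = np.empty_like(s_ord)
    for g in range(len(starts) - 1):
        i, j = starts[g], starts[g + 1]
        grad_ord[i:j] = exp_s[i:j] * suffix[g] - e_ord[i:j]
    grad = np.empty_like(grad_ord)
    grad[order] = grad_ord
    return loss, grad.reshape(scores.shape)


def survival_loss(head: str, outputs: np.ndarray, times: np.ndarray,
                  events: np.ndarray,
                  bin_idx: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Dispatch to the configured survival likelihood (summed over samples)."""
    if np.any(times <= 0):
        raise ValueError("nonpositive survival times")
    if head == "discrete_time":
        if bin_idx is None:
            raise ValueError("discrete head requires time-bin indices")
        return discrete_time_nll(outputs, bin_idx, events)
    if head == "cox":
        return cox_partial_likelihood(outputs, times, events)
    raise ValueError(f"unknown head {head!r}")


def hazards_to_risk(hazards: np.ndarray) -> np.ndarray:
    """Risk = 1 - mean predicted survival across bins; higher = worse."""
    surv = np.cumprod(1.0 - hazards, axis=1)
    return 1.0 - surv.mean(axis=1)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _embedding_dims(n_levels: dict) -> dict:
    return {f: int(min(8, max(2, np.ceil(np.sqrt(k))))) for f, k in n_levels.items()}


class SurvivalModel:
    """Encoders + attention fusion + survival head, with explicit backward."""

    def __init__(self, config: ModelConfig, feature_counts: dict,
                 n_levels: dict, n_continuous: int = 1):
        config.validate()
        self.config = config
        self.modality_order = [m for m in MODALITY_ORDER
                               if m == "clinical" or m in feature_counts]
        ss = np.random.SeedSequence(config.seed)
        init_rng, self.train_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

        emb_dims = _embedding_dims(n_levels)
        self.clinical_encoder = build_encoder(
            EncoderConfig(modality="clinical", rep_length=config.rep_length,
                          dropout_rate=config.dropout_rate,
                          embedding_dims=emb_dims),
            init_rng, n_levels=n_levels, n_continuous=n_continuous)
        self.genomic_encoders = {}
        for m in GENOMIC_MODALITIES:
            if m in feature_counts:
                self.genomic_encoders[m] = build_encoder(
                    EncoderConfig(modality=m, n_features=feature_counts[m],
                                  hidden_widths=tuple(config.hidden_widths[m]),
                                  rep_length=config.rep_length,
                                  dropout_rate=config.dropout_rate,
                                  use_batchnorm=config.use_batchnorm),
                    init_rng)

        fusion_seed = int(init_rng.integers(0, 2**31 - 1))
        self.fusion = MultiheadFusion(FusionParams(
            d=config.rep_length, H=config.heads,
            dropout_rate=config.dropout_rate, seed=fusion_seed))
        n_out = config.time_bins if config.head == "discrete_time" else 1
        self.head = nn.Dense(config.rep_length, n_out, init_rng)
        self.bin_edges: np.ndarray | None = None

    # -- forward / backward -------------------------------------------------
    def forward(self, ds: Dataset, training: bool = False) -> dict:
        rng = self.train_rng if training else None
        reps = {"clinical": self.clinical_encoder.forward(
            ds.cat, ds.cont, training=training, rng=rng)}
        for m, enc in self.genomic_encoders.items():
            reps[m] = enc.forward(ds.genomic[m], training=training, rng=rng)
        bundle = stack_representations(reps, tuple(self.modality_order))
        att = self.fusion.forward(bundle, training=training, rng=rng)
        logits = self.head.forward(att.Y)
        return {"logits": logits, "Y": att.Y, "weights": att.weights,
                "bundle": bundle}

    def backward(self, dlogits: np.ndarray) -> None:
        gY = self.head.backward(dlogits)
        gB = self.fusion.backward(gY)
        for i, m in enumerate(self.modality_order):
            if m == "clinical":
                self.clinical_encoder.backward(gB[:, i, :])
            else:
                self.genomic_encoders[m].backward(gB[:, i, :])

    def params(self) -> dict[str, nn.Param]:
        out = {f"clinical.{k}": p for k, p in self.clinical_encoder.params().items()}
        for m, enc in self.genomic_encoders.items():
            out.update({f"{m}.{k}": p for k, p in enc.params().items()})
        out.update({f"fusion.{k}": p for k, p in self.fusion.params().items()})
        out.update({f"head.{k}": p for k, p in self.head.params().items()})
        return out

    # -- prediction ---------------------------------------------------------
    def bin_index(self, times: np.ndarray) -> np.ndarray:
        if self.config.head != "discrete_time":
            raise RuntimeError("bin_index only defined for the discrete head")
        if self.bin_edges is None:
            raise RuntimeError("time bins not fitted; train first")
        return np.searchsorted(self.bin_edges, times, side="right")

    def fit_time_bins(self, times: np.ndarray) -> None:
        qs = np.arange(1, self.config.time_bins) / self.config.time_bins
        self.bin_edges = np.unique(np.quantile(times, qs))

    def predict_risk(self, ds: Dataset) -> np.ndarray:
        """Deterministic eval-mode risk; higher = worse prognosis."""
        expected = {m: v.shape[1] for m, v in ds.genomic.items()}
        have = {m: e.config.n_features for m, e in self.genomic_encoders.items()}
        if expected != have:
            raise ValueError(f"feature shape mismatch: data {expected} vs model {have}")
        out = self.forward(ds, training=False)
        if self.config.head == "discrete_time":
            h = 1.0 / (1.0 + np.exp(-out["logits"]))
            return hazards_to_risk(h)
        return out["logits"].ravel()

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data for k, p in self.params().items()}
        for m, enc in self.genomic_encoders.items():
            for i, layer in enumerate(enc.net.layers):
                if isinstance(layer, nn.BatchNorm):
                    state[f"{m}.layer{i}.running_mean"] = layer.running_mean
                    state[f"{m}.layer{i}.running_var"] = layer.running_var
        if self.bin_edges is not None:
            state["bin_edges"] = self.bin_edges
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        for k, p in params.items():
            p.data[...] = state[k]
        for m, enc in self.genomic_encoders.items():
            for i, layer in enumerate(enc.net.layers):
                if isinstance(layer, nn.BatchNorm):
                    layer.running_mean = np.array(state[f"{m}.layer{i}.running_mean"])
                    layer.running_var = np.array(state[f"{m}.layer{i}.running_var"])
        if "bin_edges" in state:
            self.bin_edges = np.array(state["bin_edges"])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    model: SurvivalModel
    config: ModelConfig
    artifacts: PreprocessArtifacts
    history: list                        # mean training loss per epoch
    ledger: PrivacyLedger
    allocation: BudgetAllocation | None = None
    val_history: list = field(default_factory=list)   # validation C-index per epoch

    def predict_risk(self, ds: Dataset) -> np.ndarray:
        return self.model.predict_risk(ds)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "params.npz", **self.model.state_dict())
        stats = {m: {"min": s.min.tolist(), "max": s.max.tolist(),
                     "var": s.var.tolist()}
                 for m, s in self.artifacts.genomic_stats.items()}
        meta = {
            "config": _config_to_dict(self.config),
            "history": self.history,
            "vocab_levels": {f: {str(k): v for k, v in t.items()}
                             for f, t in self.artifacts.vocab.levels.items()},
            "age_stats": {"min": self.artifacts.vocab.age_stats.min.tolist(),
                          "max": self.artifacts.vocab.age_stats.max.tolist(),
                          "var": self.artifacts.vocab.age_stats.var.tolist()},
            "genomic_stats": stats,
            "feature_names": self.artifacts.feature_names,
        }
        (path / "meta.json").write_text(json.dumps(meta))
        self.ledger.to_frame().to_csv(path / "ledger.csv", index=False)
        if self.allocation is not None:
            (path / "allocation.json").write_text(
                json.dumps(self.allocation.snapshot(), indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        config = _config_from_dict(meta["config"])
        vocab = ClinicalVocabulary(
            levels={f: {float(k): v for k, v in t.items()}
                    for f, t in meta["vocab_levels"].items()},
            age_stats=FeatureStats(**meta["age_stats"]))
        artifacts = PreprocessArtifacts(
            vocab=vocab,
            genomic_stats={m: FeatureStats(**s)
                           for m, s in meta["genomic_stats"].items()},
            feature_names=meta["feature_names"])
        feature_counts = {m: len(v) for m, v in meta["feature_names"].items()}
        n_levels = {f: len(t) + 1 for f, t in vocab.levels.items()}
        model = SurvivalModel(config, feature_counts, n_levels)
        with np.load(path / "params.npz") as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return cls(model=model, config=config, artifacts=artifacts,
                   history=meta["history"], ledger=PrivacyLedger())


def _config_to_dict(config: ModelConfig) -> dict:
    d = asdict(config)
    d["hidden_widths"] = {m: list(w) for m, w in d["hidden_widths"].items()}
    return d


def _config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    d["hidden_widths"] = {m: tuple(w) for m, w in d["hidden_widths"].items()}
    d["allocation"] = AllocationConfig(**d["allocation"])
    return ModelConfig(**d)


def _privatize_modality(enc, allocation: BudgetAllocation,
                        modality: str, clip_bound: float, n_batch: int,
                        rng: np.random.Generator, ledger: PrivacyLedger,
                        step: int) -> None:
    """Clip per-sample gradients, average, and add group-wise Laplace noise.

    Per-sample gradients are never materialised: for every affine layer the
    sample's contribution factorises through the cached (input, output-grad)
    pair, so the L1 norm and the weighted average come from closed forms.
    """
    layers = enc.affine_layers()
    norms = np.zeros(n_batch)
    for _, layer in layers:
        norms += layer.per_sample_l1()
    clip = np.minimum(1.0, clip_bound / np.maximum(norms, 1e-12))
    w = clip / n_batch

    groups = allocation.group_epsilons[modality]
    scales = {g: allocation.noise_scale(modality, g, clip_bound, n_batch)
              for g in groups}
    assignment = allocation.partitions[modality].assignment

    first_dense = True
    for name, layer in layers:
        grads = layer.weighted_grads(w)
        if isinstance(layer, nn.Dense):
            if first_dense:
                # rows of the first weight matrix correspond to input
                # features: noise scale set by each feature's interval
                row_scales = np.array([scales[f"T{k}"] for k in assignment])
                noise = rng.laplace(0.0, 1.0, size=grads["W"].shape)
                grads["W"] = grads["W"] + noise * row_scales[:, None]
                grads["b"] = grads["b"] + rng.laplace(
                    0.0, scales["deep"], size=grads["b"].shape)
                first_dense = False
            else:
                for key in grads:
                    grads[key] = grads[key] + rng.laplace(
                        0.0, scales["deep"], size=grads[key].shape)
            layer.W.grad[...] = grads["W"]
            layer.b.grad[...] = grads["b"]
        else:                                     # BatchNorm
            for key in grads:
                grads[key] = grads[key] + rng.laplace(
                    0.0, scales["deep"], size=grads[key].shape)
            layer.gamma.grad[...] = grads["gamma"]
            layer.beta.grad[...] = grads["beta"]

    for g, eps_g in groups.items():
        ledger.record(step, modality, g, eps_g, scales[g])


def train(ds: Dataset, config: ModelConfig,
          artifacts: PreprocessArtifacts | None = None,
          val_ds: Dataset | None = None) -> TrainedModel:
    """Fit the full model on a preprocessed training set.

    When a validation set is supplied, the validation C-index is tracked per
    epoch and the parameters of the best epoch are restored at the end
    (standard model selection; the privacy accountant covers the released
    training gradients, as usual for private training pipelines).
    """
    config.validate()
    feature_counts = {m: v.shape[1] for m, v in ds.genomic.items()}
    n_levels = {f: len(t) + 1 for f, t in
                (artifacts.vocab.levels if artifacts else {}).items()} or None
    if n_levels is None:
        n_levels = {f"field{j}": int(ds.cat[:, j].max()) + 2
                    for j in range(ds.cat.shape[1])}
    model = SurvivalModel(config, feature_counts, n_levels,
                          n_continuous=ds.cont.shape[1])
    if config.head == "discrete_time":
        model.fit_time_bins(ds.times)
        bin_idx_all = model.bin_index(ds.times)
    else:
        bin_idx_all = None

    params = model.params()
    opt_cls = nn.Adam if config.optimizer == "adam" else nn.SGD
    opt = opt_cls(params, lr=config.learning_rate,
                  weight_decay=config.weight_decay)

    ledger = PrivacyLedger()
    allocation: BudgetAllocation | None = None
    ss = np.random.SeedSequence([config.seed, 17])
    shuffle_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    ref_idx = np.arange(min(256, ds.n))
    ref_batch = ds.subset(ref_idx)

    if config.privacy:
        for enc in model.genomic_encoders.values():
            enc.set_frozen_batchnorm(True)

    history: list[float] = []
    val_history: list[float] = []
    best_val = -np.inf
    best_state: dict | None = None
    step = 0
    for epoch in range(config.epochs):
        if config.privacy and epoch % config.refresh_epochs == 0:
            rmap = feature_relevance(model, ref_batch, config.stabilizer)
            alloc_cfg = AllocationConfig(
                **{**asdict(config.allocation), "seed": config.seed})
            allocation = allocate_budgets(
                rmap.feature_scores, alloc_cfg,
                modalities=tuple(model.genomic_encoders))

        order = shuffle_rng.permutation(ds.n)
        epoch_loss = 0.0
        for start in range(0, ds.n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = ds.subset(idx)
            out = model.forward(batch, training=True)
            loss, dlogits = survival_loss(
                config.head, out["logits"], batch.times, batch.events,
                bin_idx_all[idx] if bin_idx_all is not None else None)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training loss diverged at epoch {epoch}, step {step}")
            epoch_loss += loss
            opt.zero_grad()
            model.backward(dlogits)            # sum-loss gradients
            for p in params.values():
                p.grad /= len(idx)
            if config.privacy and allocation is not None:
                for m, enc in model.genomic_encoders.items():
                    _privatize_modality(
                        enc, allocation, m, config.clip_bound,
                        len(idx), noise_rng, ledger, step)
            opt.step()
            step += 1
        history.append(epoch_loss / ds.n)
        if val_ds is not None:
            from .evaluate import c_index
            val_c = c_index(val_ds.times, val_ds.events,
                            model.predict_risk(val_ds))
            val_history.append(val_c)
            if val_c > best_val:
                best_val = val_c
                best_state = {k: v.copy() for k, v in model.state_dict().items()}

    if best_state is not None:
        model.load_state_dict(best_state)
    if config.privacy:
        for enc in model.genomic_encoders.values():
            enc.set_frozen_batchnorm(False)
    if artifacts is None:
        artifacts = PreprocessArtifacts(
            vocab=ClinicalVocabulary(levels={}, age_stats=FeatureStats(
                np.zeros(ds.cont.shape[1]), np.ones(ds.cont.shape[1]),
                np.ones(ds.cont.shape[1]))),
            genomic_stats={}, feature_names={})
    return TrainedModel(model=model, config=config, artifacts=artifacts,
                        history=history, ledger=ledger, allocation=allocation,
                        val_history=val_history)


def predict_risk(trained: TrainedModel, ds: Dataset) -> np.ndarray:
    return trained.predict_risk(ds)


# ---------------------------------------------------------------------------
# Auxiliary survival-status classifier (3 fully connected layers)
# ---------------------------------------------------------------------------

class StatusClassifier:
    """Binary survival-status classifier on fused features (3 FC layers)."""

    def __init__(self, n_in: int, hidden: tuple[int, int] = (32, 16),
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.net = nn.MLP([
            nn.Dense(n_in, hidden[0], rng), nn.ReLU(),
            nn.Dense(hidden[0], hidden[1], rng), nn.ReLU(),
            nn.Dense(hidden[1], 1, rng),
        ])

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 200,
            lr: float = 1e-2, batch_size: int = 256, seed: int = 0
            ) -> "StatusClassifier":
        if len(np.unique(y)) < 2:
            raise ValueError("status classifier needs both classes present")
        rng = np.random.default_rng(seed)
        opt = nn.Adam(self.net.params(), lr=lr)
        for _ in range(epochs):
            order = rng.permutation(len(y))
            for start in range(0, len(y), batch_size):
                idx = order[start:start + batch_size]
                z = self.net.forward(X[idx], training=True, rng=rng).ravel()
                p = 1.0 / (1.0 + np.exp(-z))
                grad = ((p - y[idx]) / len(idx)).reshape(-1, 1)
                opt.zero_grad()
                self.net.backward(grad)
                opt.step()
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = self.net.forward(X, training=False).ravel()
        return (z > 0).astype(int)


def classify_status(trained: TrainedModel, train_ds: Dataset, test_ds: Dataset,
                    hidden: tuple[int, int] = (32, 16), epochs: int = 200,
                    seed: int = 0) -> tuple[StatusClassifier, float]:
    """Train the 3-FC-layer status classifier on fused features; report accuracy.

    Deceased patients are labelled 1 and surviving patients 0.
    """
    from .evaluate import accuracy
    Y_train = trained.model.forward(train_ds, training=False)["Y"]
    Y_test = trained.model.forward(test_ds, training=False)["Y"]
    clf = StatusClassifier(Y_train.shape[1], hidden=hidden, seed=seed)
    clf.fit(Y_train, train_ds.status_labels.astype(float), epochs=epochs,
            seed=seed)
    acc = accuracy(test_ds.status_labels, clf.predict(Y_test))
    return clf, acc
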