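"""Synthetic multimodal survival cohorts with known ground truth.

The generator emulates the structure of a pan-cancer multi-omics cohort: four
modality blocks (clinical categoricals + age, mRNA, miRNA, CNV feature
matrices), right-censored survival outcomes, per-patient missing modalities,
and a planted minority of prognostic features per modality. Survival times
follow an exponential proportional-hazards model, so the true risk ordering is
known in closed form and every downstream stage (encoders, fusion, relevance
scoring, private training, evaluation) can be tested without any external
download.

Censoring is independent uniform on ``(0, c_max)`` with ``c_max`` calibrated
numerically (bisection on the closed-form censoring probability) so the
expected censored fraction equals ``censor_rate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "CohortSpec",
    "SurvivalRecord",
    "ModalityBlock",
    "GroundTruth",
    "CohortSpecError",
    "FormatError",
    "CLINICAL_FIELDS",
    "MODALITY_ORDER",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "records_to_arrays",
]

MODALITY_ORDER = ("clinical", "mRNA", "miRNA", "CNV")
CLINICAL_CATEGORICAL = ("cancer_type", "gender", "race", "histological_type")
CLINICAL_CONTINUOUS = ("age",)
CLINICAL_FIELDS = CLINICAL_CATEGORICAL + CLINICAL_CONTINUOUS

# Baseline hazard: median survival of two years for a patient at the cohort
# mean of the linear predictor (days).
_BASELINE_HAZARD = np.log(2.0) / 730.0


class CohortSpecError(ValueError):
    """Invalid cohort specification."""


class FormatError(ValueError):
    """Malformed on-disk cohort."""


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror a TCGA-like pan-cancer cohort: 11,094 patients, 1579 mRNA /
    743 miRNA / 2711 CNV features, per-modality missing-sample rates of
    3.1 / 9.7 / 8.3 %, and a clinical block of four categorical fields plus
    age. ``effect_size`` is the log-hazard weight shared by all planted
    features.
    """

    n_patients: int = 11094
    dims: dict = field(default_factory=lambda: {"mRNA": 1579, "miRNA": 743, "CNV": 2711})
    n_informative: dict = field(default_factory=lambda: {"mRNA": 10, "miRNA": 10, "CNV": 10})
    effect_size: float = 1.0
    censor_rate: float = 0.3
    missing_rate: dict = field(
        default_factory=lambda: {"mRNA": 0.031, "miRNA": 0.097, "CNV": 0.083})
    n_categories: dict = field(
        default_factory=lambda: {"cancer_type": 20, "gender": 2,
                                 "race": 4, "histological_type": 10})
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise CohortSpecError("n_patients must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise CohortSpecError("censor_rate must lie in [0, 1)")
        for m, k in self.n_informative.items():
            if m not in self.dims:
                raise CohortSpecError(f"n_informative names unknown modality {m!r}")
            if k > self.dims[m]:
                raise CohortSpecError(
                    f"n_informative[{m!r}]={k} exceeds dims[{m!r}]={self.dims[m]}")
        for m, r in self.missing_rate.items():
            if not 0.0 <= r < 1.0:
                raise CohortSpecError(f"missing_rate[{m!r}] must lie in [0, 1)")
        for f, k in self.n_categories.items():
            if f not in CLINICAL_CATEGORICAL:
                raise CohortSpecError(f"unknown clinical field {f!r}")
            if k < 1:
                raise CohortSpecError(f"n_categories[{f!r}] must be >= 1")


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float          # days of follow-up
    event: int           # 1 = death observed, 0 = right-censored
    status_label: int    # binary survival-status label; equals event

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError(f"follow-up time must be positive, got {self.time}")


@dataclass
class ModalityBlock:
    name: str
    values: np.ndarray            # patients x features
    feature_names: list[str]
    missing_mask: np.ndarray      # bool per patient; True = modality absent

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape[0] != self.missing_mask.shape[0]:
            raise ValueError("missing_mask length must equal row count")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must equal column count")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class GroundTruth:
    informative_indices: dict      # modality -> np.ndarray of column indices
    true_linear_predictor: np.ndarray


def _calibrate_censor_window(hazards: np.ndarray, censor_rate: float) -> float:
    """Uniform-censoring upper bound achieving the target censored fraction.

    With ``T ~ Exp(h)`` and ``C ~ U(0, c)``, ``P(T > C) = (1 - e^{-hc})/(hc)``;
    the cohort-average of that expression is decreasing in ``c`` and is solved
    for the target rate by bisection.
    """

    def frac(c: float) -> float:
        hc = hazards * c
        return float(np.mean(-np.expm1(-hc) / hc)) - censor_rate

    scale = 1.0 / np.median(hazards)
    lo, hi = 1e-9 * scale, 1e9 * scale
    return brentq(frac, lo, hi, xtol=1e-12 * scale)


def generate_cohort(spec: CohortSpec) -> tuple[list[ModalityBlock], list[SurvivalRecord], GroundTruth]:
    """Draw one cohort. Bitwise-reproducible for a fixed ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    # Clinical covariates.
    cat_codes = {f: rng.integers(0, spec.n_categories[f], size=n)
                 for f in CLINICAL_CATEGORICAL}
    age = rng.uniform(30.0, 85.0, size=n)

    # Genomic features and latent (pre-masking) values used for the hazard.
    latent: dict[str, np.ndarray] = {}
    informative: dict[str, np.ndarray] = {}
    for m in ("mRNA", "miRNA", "CNV"):
        p = spec.dims.get(m, 0)
        latent[m] = rng.standard_normal((n, p))
        k = spec.n_informative.get(m, 0)
        informative[m] = np.sort(rng.choice(p, size=k, replace=False)) if k else np.empty(0, int)

    # The planted clinical signal exercises both encoding paths: one
    # continuous variable (standardised age) and one categorical level.
    age_std = (age - age.mean()) / age.std()
    cancer_flag = (cat_codes["cancer_type"] == 0).astype(float)
    lp = spec.effect_size * (age_std + cancer_flag)
    for m in ("mRNA", "miRNA", "CNV"):
        if informative[m].size:
            lp = lp + spec.effect_size * latent[m][:, informative[m]].sum(axis=1)

    hazards = _BASELINE_HAZARD * np.exp(lp - lp.mean())
    t_event = rng.exponential(1.0, size=n) / hazards
    if spec.censor_rate > 0:
        c_max = _calibrate_censor_window(hazards, spec.censor_rate)
        t_cens = rng.uniform(0.0, c_max, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time = t_event
        event = np.ones(n, dtype=int)
    time = np.maximum(time, 1e-6)

    records = [SurvivalRecord(patient_id=f"P{i:05d}", time=float(time[i]),
                              event=int(event[i]), status_label=int(event[i]))
               for i in range(n)]

    blocks: list[ModalityBlock] = []
    clin_values = np.column_stack(
        [cat_codes[f].astype(float) for f in CLINICAL_CATEGORICAL] + [age])
    clin_missing = rng.random(n) < spec.missing_rate.get("clinical", 0.0)
    clin_values[clin_missing] = 0.0
    blocks.append(ModalityBlock("clinical", clin_values,
                                list(CLINICAL_FIELDS), clin_missing))
    for m in ("mRNA", "miRNA", "CNV"):
        vals = latent[m].copy()
        miss = rng.random(n) < spec.missing_rate.get(m, 0.0)
        vals[miss] = 0.0
        names = [f"{m}_f{j}" for j in range(vals.shape[1])]
        blocks.append(ModalityBlock(m, vals, names, miss))

    truth = GroundTruth(
        informative_indices={
            "clinical": np.array([0, 4]),  # cancer_type level flag, age
            **{m: informative[m] for m in ("mRNA", "miRNA", "CNV")},
        },
        true_linear_predictor=lp,
    )
    return blocks, records, truth


def records_to_arrays(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    return times, events


# ---------------------------------------------------------------------------
# On-disk layout: a directory with a manifest, one CSV per modality (absent
# rows for patients missing the modality), a mask file, and an outcomes table.
# ---------------------------------------------------------------------------

def write_cohort(blocks: list[ModalityBlock], records: list[SurvivalRecord],
                 path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ids = [r.patient_id for r in records]

    outcomes = pd.DataFrame({"patient_id": ids,
                             "time": [r.time for r in records],
                             "event": [r.event for r in records]})
    # %.17g round-trips IEEE doubles exactly
    outcomes.to_csv(path / "outcomes.csv", index=False, float_format="%.17g")

    masks: dict[str, list[str]] = {}
    manifest = {"modalities": {}, "outcomes": "outcomes.csv", "masks": "masks.json"}
    for block in blocks:
        if block.n_patients != len(records):
            raise FormatError(
                f"block {block.name!r} has {block.n_patients} rows, cohort has {len(records)}")
        fname = f"{block.name}.csv"
        keep = ~block.missing_mask
        df = pd.DataFrame(block.values[keep], columns=block.feature_names)
        df.insert(0, "patient_id", np.asarray(ids)[keep])
        df.to_csv(path / fname, index=False, float_format="%.17g")
        masks[block.name] = [ids[i] for i in np.flatnonzero(block.missing_mask)]
        manifest["modalities"][block.name] = fname
    (path / "masks.json").write_text(json.dumps(masks, indent=1))
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def read_cohort(path: str | Path) -> tuple[list[ModalityBlock], list[SurvivalRecord]]:
    path = Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
    except FileNotFoundError as exc:
        raise FormatError(f"no manifest.json under {path}") from exc

    outcomes = pd.read_csv(path / manifest["outcomes"],
                           float_precision="round_trip")
    for col in ("patient_id", "time", "event"):
        if col not in outcomes.columns:
            raise FormatError(f"outcomes table lacks required column {col!r}")
    records = [SurvivalRecord(patient_id=str(r.patient_id), time=float(r.time),
                              event=int(r.event), status_label=int(r.event))
               for r in outcomes.itertuples(index=False)]
    ids = [r.patient_id for r in records]
    row_of = {pid: i for i, pid in enumerate(ids)}

    masks = json.loads((path / manifest["masks"]).read_text())
    blocks = []
    for name, fname in manifest["modalities"].items():
        df = pd.read_csv(path / fname, float_precision="round_trip")
        if "patient_id" not in df.columns:
            raise FormatError(f"modality table {fname} lacks patient_id")
        missing_ids = set(masks.get(name, []))
        if len(df) + len(missing_ids) != len(records):
            raise FormatError(
                f"modality {name!r}: {len(df)} rows + {len(missing_ids)} masked "
                f"!= cohort size {len(records)}")
        feature_names = [c for c in df.columns if c != "patient_id"]
        values = np.zeros((len(records), len(feature_names)))
        mask = np.zeros(len(records), dtype=bool)
        for pid in missing_ids:
            if pid not in row_of:
                raise FormatError(f"masked patient {pid!r} not in outcomes")
            mask[row_of[pid]] = True
        rows = [row_of[pid] for pid in df["patient_id"].astype(str)]
        values[rows] = df[feature_names].to_numpy(dtype=float)
        blocks.append(ModalityBlock(name, values, feature_names, mask))
    return blocks, records
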