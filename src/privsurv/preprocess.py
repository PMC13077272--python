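"""Screening, normalisation, imputation and clinical encoding.

The pipeline mirrors standard multi-omics survival preprocessing: features are
screened by a population-variance threshold (defaults 7 for mRNA and 0.2 for
CNV; miRNA is not thresholded), continuous features are min-max normalised to
[0, 1] with statistics frozen on the training cohort, absent modalities are
zero-vector imputed, and clinical categoricals are mapped to integer indices
through a fitted vocabulary with a reserved unknown index for inference-time
levels. External cohorts are aligned to the training feature list by
reindexing with zero fill — the same convention as missing-modality
imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import (CLINICAL_CATEGORICAL, CLINICAL_CONTINUOUS,
                        ModalityBlock)

__all__ = [
    "PreprocessConfig",
    "FeatureStats",
    "ClinicalVocabulary",
    "variance_filter",
    "minmax_normalize",
    "impute_missing",
    "encode_clinical",
    "align_external_features",
]

DEFAULT_VARIANCE_THRESHOLDS = {"mRNA": 7.0, "CNV": 0.2}


@dataclass(frozen=True)
class PreprocessConfig:
    variance_threshold: dict = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_THRESHOLDS))
    normalize: bool = True
    clinical_categorical_fields: tuple = CLINICAL_CATEGORICAL
    clinical_continuous_fields: tuple = CLINICAL_CONTINUOUS

    def __post_init__(self):
        for m, t in self.variance_threshold.items():
            if t < 0:
                raise ValueError(f"variance threshold for {m!r} must be >= 0")


@dataclass
class FeatureStats:
    """Per-feature min/max/variance frozen on a reference (training) cohort."""

    min: np.ndarray
    max: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        self.min = np.asarray(self.min, dtype=float)
        self.max = np.asarray(self.max, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if np.any(self.max < self.min):
            raise ValueError("max < min in FeatureStats")

    @classmethod
    def fit(cls, block: ModalityBlock) -> "FeatureStats":
        """Statistics over non-missing patients (population variance)."""
        present = block.values[~block.missing_mask]
        if present.shape[0] == 0:
            z = np.zeros(block.n_features)
            return cls(z, z, z)
        return cls(present.min(axis=0), present.max(axis=0), present.var(axis=0))


def variance_filter(block: ModalityBlock, threshold: float,
                    stats: FeatureStats | None = None) -> ModalityBlock:
    """Keep exactly the features with variance strictly above ``threshold``.

    Variance is the population variance over non-missing patients; column
    order is preserved. ``stats`` may carry frozen training-cohort variances
    for reuse on an external cohort.
    """
    if stats is None:
        stats = FeatureStats.fit(block)
    keep = stats.var > threshold
    if not keep.any():
        warnings.warn(
            f"variance_filter left no features in modality {block.name!r} "
            f"at threshold {threshold}", stacklevel=2)
    names = [n for n, k in zip(block.feature_names, keep) if k]
    return ModalityBlock(block.name, block.values[:, keep], names,
                         block.missing_mask.copy())


def minmax_normalize(block: ModalityBlock, stats: FeatureStats) -> ModalityBlock:
    """Column-wise ``(x - min) / (max - min)`` with clipping to [0, 1].

    Constant columns (max == min) map to 0 with a warning rather than being
    dropped, so feature shapes stay stable once statistics are frozen.
    """
    span = stats.max - stats.min
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s) in {block.name!r} "
            "mapped to 0", stacklevel=2)
    safe = np.where(constant, 1.0, span)
    values = np.clip((block.values - stats.min) / safe, 0.0, 1.0)
    values[:, constant] = 0.0
    values[block.missing_mask] = 0.0
    return ModalityBlock(block.name, values, list(block.feature_names),
                         block.missing_mask.copy())


def impute_missing(block: ModalityBlock) -> ModalityBlock:
    """Zero-vector imputation: masked rows become all-zero; mask retained."""
    values = block.values.copy()
    values[block.missing_mask] = 0.0
    return ModalityBlock(block.name, values, list(block.feature_names),
                         block.missing_mask.copy())


@dataclass
class ClinicalVocabulary:
    """Fitted level->index maps for categorical clinical fields.

    The reserved unknown index of each field is ``len(levels)``; it is only
    reachable at inference, when an unseen level appears.
    """

    levels: dict                 # field -> {level_code: index}
    age_stats: FeatureStats

    @classmethod
    def fit(cls, block: ModalityBlock,
            config: PreprocessConfig | None = None) -> "ClinicalVocabulary":
        config = config or PreprocessConfig()
        present = ~block.missing_mask
        col = {n: i for i, n in enumerate(block.feature_names)}
        levels = {}
        for f in config.clinical_categorical_fields:
            seen = np.unique(block.values[present, col[f]])
            levels[f] = {float(v): i for i, v in enumerate(seen)}
        age_cols = [col[f] for f in config.clinical_continuous_fields]
        age_vals = block.values[present][:, age_cols]
        age_stats = FeatureStats(age_vals.min(axis=0), age_vals.max(axis=0),
                                 age_vals.var(axis=0))
        return cls(levels=levels, age_stats=age_stats)

    def n_levels(self, f: str) -> int:
        return len(self.levels[f]) + 1  # + reserved unknown


def encode_clinical(block: ModalityBlock, vocab: ClinicalVocabulary,
                    config: PreprocessConfig | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Map the clinical block to (categorical index matrix, continuous matrix).

    Returns shapes ``(patients, n_categorical)`` and
    ``(patients, n_continuous)``; continuous fields are min-max normalised
    with the vocabulary's frozen statistics. Unseen categorical levels map to
    the reserved unknown index with a warning.
    """
    config = config or PreprocessConfig()
    col = {n: i for i, n in enumerate(block.feature_names)}
    n = block.n_patients
    cat = np.zeros((n, len(config.clinical_categorical_fields)), dtype=int)
    for j, f in enumerate(config.clinical_categorical_fields):
        table = vocab.levels[f]
        unknown = len(table)
        vals = block.values[:, col[f]]
        idx = np.array([table.get(float(v), unknown) for v in vals])
        if np.any(idx == unknown):
            warnings.warn(
                f"{int((idx == unknown).sum())} unseen level(s) in clinical "
                f"field {f!r} mapped to the reserved unknown index", stacklevel=2)
        cat[:, j] = idx

    cols = [col[f] for f in config.clinical_continuous_fields]
    span = vocab.age_stats.max - vocab.age_stats.min
    safe = np.where(span == 0, 1.0, span)
    cont = np.clip((block.values[:, cols] - vocab.age_stats.min) / safe, 0.0, 1.0)
    cont[:, span == 0] = 0.0
    cont[block.missing_mask] = 0.0
    return cat, cont


def align_external_features(block: ModalityBlock,
                            reference_feature_names: list[str]) -> ModalityBlock:
    """Reindex an external block to the training feature list.

    Features absent in the external cohort are zero-filled; output columns are
    exactly ``reference_feature_names`` in that order. An overlap below 50%
    triggers a warning (not an error).
    """
    have = {n: i for i, n in enumerate(block.feature_names)}
    overlap = sum(1 for n in reference_feature_names if n in have)
    if reference_feature_names and overlap < 0.5 * len(reference_feature_names):
        warnings.warn(
            f"external cohort shares only {overlap}/{len(reference_feature_names)} "
            f"features with the reference for modality {block.name!r}", stacklevel=2)
    values = np.zeros((block.n_patients, len(reference_feature_names)))
    for j, name in enumerate(reference_feature_names):
        if name in have:
            values[:, j] = block.values[:, have[name]]
    return ModalityBlock(block.name, values, list(reference_feature_names),
                         block.missing_mask.copy())
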