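"""Variance screening, normalisation, imputation, encoding, alignment."""

import numpy as np
import pytest

from privsurv.preprocess import (ClinicalVocabulary, FeatureStats,
                                 PreprocessConfig, align_external_features,
                                 encode_clinical, impute_missing,
                                 minmax_normalize, variance_filter)
from privsurv.synthetic import ModalityBlock


def block(values, names=None, mask=None, name="mRNA"):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    mask = np.zeros(values.shape[0], bool) if mask is None else np.asarray(mask)
    return ModalityBlock(name, values, names, mask)


class TestVarianceFilter:
    def test_keeps_exactly_features_above_threshold(self):
        # population variances 0.50, 0.05, 0.30 by construction
        base = np.array([0.0, 1.0, 2.0, 1.0])          # variance 0.5
        cols = np.column_stack([base, base * np.sqrt(0.1), base * np.sqrt(0.6)])
        # independent oracle: population variance by hand
        hand_var = ((cols - cols.mean(axis=0)) ** 2).sum(axis=0) / 4
        assert hand_var == pytest.approx([0.50, 0.05, 0.30])
        out = variance_filter(block(cols, ["f1", "f2", "f3"]), 0.2)
        assert out.feature_names == ["f1", "f3"]
        assert np.array_equal(out.values, cols[:, [0, 2]])

    def test_zero_threshold_keeps_all_nonconstant(self):
        rng = np.random.default_rng(0)
        b = block(rng.random((6, 4)))
        assert variance_filter(b, 0.0).feature_names == b.feature_names

    def test_constant_feature_dropped(self):
        vals = np.column_stack([np.full(5, 3.0), np.arange(5.0)])
        out = variance_filter(block(vals, ["const", "ramp"]), 0.2)
        assert out.feature_names == ["ramp"]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        b = block(rng.random((8, 6)) * 3)
        once = variance_filter(b, 0.4)
        twice = variance_filter(once, 0.4)
        assert twice.feature_names == once.feature_names
        assert np.array_equal(twice.values, once.values)

    def test_masked_rows_excluded_from_variance(self):
        vals = np.array([[0.0], [1.0], [2.0], [100.0]])
        mask = np.array([False, False, False, True])
        # with the outlier masked the population variance over present rows
        # is 2/3, below a threshold of 1
        out = variance_filter(block(vals, ["f"], mask), 1.0)
        assert out.feature_names == []

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning, match="no features"):
            out = variance_filter(block(np.ones((4, 2))), 0.2)
        assert out.n_features == 0


class TestMinmaxNormalize:
    def test_affine_map_to_unit_interval(self):
        b = block(np.array([[2.0], [4.0], [6.0]]))
        out = minmax_normalize(b, FeatureStats.fit(b))
        assert np.allclose(out.values.ravel(), [0.0, 0.5, 1.0])

    def test_identity_on_unit_interval_column(self):
        b = block(np.array([[0.0], [0.25], [1.0]]))
        out = minmax_normalize(b, FeatureStats.fit(b))
        assert np.allclose(out.values, b.values)

    def test_external_values_clipped(self):
        stats = FeatureStats(min=np.array([2.0]), max=np.array([6.0]),
                             var=np.array([1.0]))
        out = minmax_normalize(block(np.array([[8.0], [0.0]])), stats)
        assert np.allclose(out.values.ravel(), [1.0, 0.0])

    def test_constant_column_maps_to_zero_with_warning(self):
        b = block(np.full((3, 1), 5.0))
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize(b, FeatureStats.fit(b))
        assert np.all(out.values == 0.0)

    def test_order_preserving_within_column(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(30, 3))
        b = block(vals)
        out = minmax_normalize(b, FeatureStats.fit(b))
        for j in range(3):
            assert np.array_equal(np.argsort(out.values[:, j], kind="stable"),
                                  np.argsort(vals[:, j], kind="stable"))


class TestImputeMissing:
    def test_masked_rows_become_zero_vectors(self):
        vals = np.ones((4, 743))
        mask = np.array([False, True, False, False])
        out = impute_missing(block(vals, mask=mask, name="miRNA"))
        assert np.all(out.values[1] == 0.0)
        assert out.values.shape[1] == 743
        assert np.array_equal(out.missing_mask, mask)

    def test_unmasked_rows_unchanged(self):
        rng = np.random.default_rng(3)
        vals = rng.random((5, 4))
        mask = np.array([False, True, False, True, False])
        out = impute_missing(block(vals.copy(), mask=mask))
        assert np.array_equal(out.values[~mask], vals[~mask])

    def test_all_missing_gives_zero_matrix(self):
        out = impute_missing(block(np.ones((3, 2)), mask=np.ones(3, bool)))
        assert np.all(out.values == 0.0)


class TestClinicalEncoding:
    def make_clinical(self, cats, age):
        n = len(age)
        vals = np.column_stack([np.asarray(c, float) for c in cats] +
                               [np.asarray(age, float)])
        return ModalityBlock("clinical", vals,
                             ["cancer_type", "gender", "race",
                              "histological_type", "age"],
                             np.zeros(n, bool))

    def test_vocabulary_lookup_and_age_normalisation(self):
        b = self.make_clinical(
            [[0, 1, 0], [0, 1, 1], [2, 0, 1], [1, 1, 0]], [40.0, 60.0, 80.0])
        vocab = ClinicalVocabulary.fit(b)
        cat, cont = encode_clinical(b, vocab)
        assert cat.shape == (3, 4) and cont.shape == (3, 1)
        assert vocab.levels["gender"] == {0.0: 0, 1.0: 1}
        assert cat[:, 1].tolist() == [0, 1, 1]          # F/M-style lookup
        assert np.allclose(cont.ravel(), [0.0, 0.5, 1.0])

    def test_unseen_level_maps_to_reserved_index_with_warning(self):
        fit_b = self.make_clinical(
            [[0, 1], [0, 1], [1, 0], [0, 1]], [50.0, 70.0])
        vocab = ClinicalVocabulary.fit(fit_b)
        new_b = self.make_clinical(
            [[5, 0], [0, 1], [1, 0], [0, 1]], [55.0, 60.0])
        with pytest.warns(UserWarning, match="unseen"):
            cat, _ = encode_clinical(new_b, vocab)
        assert cat[0, 0] == len(vocab.levels["cancer_type"])


class TestAlignExternal:
    def test_reindex_with_zero_fill(self):
        b = block(np.array([[1.0, 3.0], [2.0, 4.0]]), ["g1", "g3"])
        out = align_external_features(b, ["g1", "g2", "g3"])
        assert out.feature_names == ["g1", "g2", "g3"]
        assert np.array_equal(out.values,
                              [[1.0, 0.0, 3.0], [2.0, 0.0, 4.0]])

    def test_identical_sets_identity_up_to_order(self):
        b = block(np.array([[1.0, 2.0]]), ["a", "b"])
        out = align_external_features(b, ["b", "a"])
        assert np.array_equal(out.values, [[2.0, 1.0]])

    def test_empty_overlap_all_zero_with_warning(self):
        b = block(np.ones((2, 2)), ["x", "y"])
        with pytest.warns(UserWarning, match="shares only"):
            out = align_external_features(b, ["g1", "g2"])
        assert np.all(out.values == 0.0)


def test_config_rejects_negative_threshold():
    with pytest.raises(ValueError, match=">= 0"):
        PreprocessConfig(variance_threshold={"mRNA": -1.0})
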