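"""Survival losses, risk prediction, training loop, checkpointing, classifier."""

import dataclasses
import math

import numpy as np
import pytest

from privsurv.privacy import accountant_report
from privsurv.survival import (StatusClassifier, TrainedModel,
                               cox_partial_likelihood, discrete_time_nll,
                               hazards_to_risk, prepare_dataset, survival_loss,
                               train)
from conftest import make_tiny_config


def logit(p):
    return np.log(p / (1.0 - p))


class TestDiscreteTimeNLL:
    def test_certain_event_in_single_bin_has_zero_loss(self):
        loss, _ = discrete_time_nll(np.array([[40.0]]),          # hazard ~ 1
                                    np.array([0]), np.array([1]))
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_certain_survival_of_censored_patient_has_zero_loss(self):
        loss, _ = discrete_time_nll(np.full((1, 3), -40.0),      # hazards ~ 0
                                    np.array([2]), np.array([0]))
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_three_patient_hand_computed_likelihood(self):
        h = np.array([[0.2, 0.5, 0.1],
                      [0.3, 0.4, 0.9],
                      [0.6, 0.2, 0.3]])
        bins = np.array([1, 2, 0])
        events = np.array([1, 0, 1])
        # independent term-by-term evaluation:
        # p1: event bin 1 -> log(1-0.2) + log(0.5)
        # p2: censored bin 2 -> log(1-0.3) + log(1-0.4) + log(1-0.9)
        # p3: event bin 0 -> log(0.6)
        expected = -(math.log(0.8) + math.log(0.5)
                     + math.log(0.7) + math.log(0.6) + math.log(0.1)
                     + math.log(0.6))
        loss, _ = discrete_time_nll(logit(h), bins, events)
        assert loss == pytest.approx(expected, rel=1e-9)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(4, 3))
        bins = np.array([0, 2, 1, 2])
        events = np.array([1, 0, 1, 1])
        _, grad = discrete_time_nll(z, bins, events)
        for i, j in [(0, 0), (1, 2), (2, 1), (3, 2), (3, 0)]:
            eps = 1e-6
            zp, zm = z.copy(), z.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            num = (discrete_time_nll(zp, bins, events)[0]
                   - discrete_time_nll(zm, bins, events)[0]) / (2 * eps)
            assert grad[i, j] == pytest.approx(num, abs=1e-6)


class TestCoxPartialLikelihood:
    def test_two_patient_hand_computed_value(self):
        s = np.array([0.7, -0.2])
        times = np.array([1.0, 2.0])
        events = np.array([1, 1])
        expected = -(s[0] - math.log(math.exp(s[0]) + math.exp(s[1]))) \
                   - (s[1] - math.log(math.exp(s[1])))
        loss, _ = cox_partial_likelihood(s, times, events)
        assert loss == pytest.approx(expected, rel=1e-9)

    def test_gradient_matches_finite_differences_with_ties(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=6)
        times = np.array([3.0, 1.0, 3.0, 2.0, 1.0, 5.0])   # tied times
        events = np.array([1, 1, 0, 1, 0, 1])
        _, grad = cox_partial_likelihood(s, times, events)
        for i in range(6):
            eps = 1e-6
            sp, sm = s.copy(), s.copy()
            sp[i] += eps
            sm[i] -= eps
            num = (cox_partial_likelihood(sp, times, events)[0]
                   - cox_partial_likelihood(sm, times, events)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-6)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            survival_loss("cox", np.zeros(2), np.array([0.0, 1.0]),
                          np.array([1, 1]))


class TestRiskSummary:
    def test_zero_hazards_give_minimal_risk(self):
        assert np.all(hazards_to_risk(np.zeros((3, 5))) == 0.0)

    def test_raising_any_hazard_raises_risk(self):
        h = np.full((1, 4), 0.2)
        base = hazards_to_risk(h)[0]
        for j in range(4):
            h2 = h.copy()
            h2[0, j] = 0.5
            assert hazards_to_risk(h2)[0] > base


@pytest.fixture(scope="module")
def trained_tiny(tiny_cohort):
    blocks, records, _ = tiny_cohort
    ds, artifacts = prepare_dataset(blocks, records)
    config = make_tiny_config(epochs=4)
    return train(ds, config, artifacts), ds


class TestTraining:
    def test_loss_history_is_finite_and_decreasing_overall(self, trained_tiny):
        trained, _ = trained_tiny
        assert all(np.isfinite(trained.history))
        assert trained.history[-1] < trained.history[0]

    def test_identical_patients_get_identical_risks(self, trained_tiny):
        trained, ds = trained_tiny
        twice = ds.subset(np.array([0, 0, 5]))
        risks = trained.predict_risk(twice)
        assert risks[0] == risks[1]

    def test_prediction_deterministic_in_eval_mode(self, trained_tiny):
        trained, ds = trained_tiny
        assert np.array_equal(trained.predict_risk(ds), trained.predict_risk(ds))

    def test_feature_shape_mismatch_rejected(self, trained_tiny):
        trained, ds = trained_tiny
        bad = dataclasses.replace(
            ds, genomic={m: v[:, :-1] for m, v in ds.genomic.items()})
        with pytest.raises(ValueError, match="shape mismatch"):
            trained.predict_risk(bad)

    def test_checkpoint_round_trip_preserves_predictions_bitwise(
            self, trained_tiny, tmp_path):
        trained, ds = trained_tiny
        before = trained.predict_risk(ds)
        trained.save(tmp_path / "ckpt")
        loaded = TrainedModel.load(tmp_path / "ckpt")
        assert np.array_equal(loaded.predict_risk(ds), before)

    def test_fixed_seed_training_is_reproducible(self, tiny_cohort):
        blocks, records, _ = tiny_cohort
        ds, artifacts = prepare_dataset(blocks, records)
        config = make_tiny_config(epochs=2)
        r1 = train(ds, config, artifacts).predict_risk(ds)
        r2 = train(ds, config, artifacts).predict_risk(ds)
        assert np.array_equal(r1, r2)


class TestPrivateTraining:
    def test_ledger_filled_and_within_budget(self, tiny_cohort):
        blocks, records, _ = tiny_cohort
        ds, artifacts = prepare_dataset(blocks, records)
        config = make_tiny_config(epochs=2, privacy=True)
        trained = train(ds, config, artifacts)
        report = accountant_report(trained.ledger,
                                   config.allocation.global_epsilon)
        assert report["within_budget"]
        assert report["per_period_total"] == pytest.approx(0.8, abs=1e-9)
        assert report["naive_across_training"] > report["per_period_total"]

    def test_unprotected_branch_bitequals_noiseless_path(self, tiny_cohort):
        """One full-batch step: clinical/fusion/head updates carry no noise."""
        blocks, records, _ = tiny_cohort
        ds, artifacts = prepare_dataset(blocks, records)
        base = make_tiny_config(epochs=1, batch_size=512, use_batchnorm=False,
                                dropout_rate=0.0)
        off = train(ds, base, artifacts)
        on = train(ds, dataclasses.replace(base, privacy=True), artifacts)
        for k, p in off.model.params().items():
            q = on.model.params()[k]
            if k.split(".")[0] in ("clinical", "fusion", "head"):
                assert np.array_equal(p.data, q.data), k
            else:
                assert not np.array_equal(p.data, q.data), k

    def test_infinite_budget_limit_recovers_clipped_average(self, tiny_cohort):
        """With a huge global budget the noisy update matches the noiseless one.

        Uses plain SGD so the vanishing Laplace noise (scale 2C/(|L| eps))
        translates directly into a vanishing parameter difference, and a clip
        bound above every per-sample norm so clipping is inactive.
        """
        blocks, records, _ = tiny_cohort
        ds, artifacts = prepare_dataset(blocks, records)
        base = make_tiny_config(epochs=1, batch_size=512, use_batchnorm=False,
                                dropout_rate=0.0, clip_bound=1e4,
                                optimizer="sgd")
        off = train(ds, base, artifacts)
        cfg_on = dataclasses.replace(base, privacy=True,
                                     allocation=dataclasses.replace(
                                         base.allocation, global_epsilon=1e9))
        on = train(ds, cfg_on, artifacts)
        for k, p in off.model.params().items():
            assert np.allclose(on.model.params()[k].data, p.data,
                               atol=1e-6), k


class TestStatusClassifier:
    def test_linearly_separable_features_reach_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2.0, 0.3, size=(40, 4)),
                       rng.normal(2.0, 0.3, size=(40, 4))])
        y = np.repeat([0.0, 1.0], 40)
        clf = StatusClassifier(4, seed=1).fit(X, y, epochs=300)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 6))
        y = rng.integers(0, 2, 400).astype(float)
        clf = StatusClassifier(6, seed=10).fit(X[:200], y[:200], epochs=100)
        held_out = np.mean(clf.predict(X[200:]) == y[200:])
        assert held_out == pytest.approx(0.5, abs=0.08)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            StatusClassifier(3).fit(np.zeros((5, 3)), np.zeros(5))
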