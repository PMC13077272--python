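"""Budget partitioning, the eta map, clipping, Laplace noise, accounting."""

import numpy as np
import pytest
from scipy import stats as sps

from privsurv.privacy import (AllocationConfig, PrivacyLedger,
                              accountant_report, allocate_budgets,
                              clip_per_sample_gradient, eta_map, eta_sequence,
                              laplace_sample, partition_intervals)


class TestPartitionIntervals:
    def test_quartiles_of_1_to_100(self):
        part = partition_intervals(np.arange(1, 101), 4)
        assert part.n == 4
        # T_1 = (75, 100], T_4 = [1, 25]
        assert set(part.members(1) + 1) == set(range(76, 101))
        assert set(part.members(4) + 1) == set(range(1, 26))

    def test_every_feature_in_exactly_one_interval(self):
        rng = np.random.default_rng(0)
        scores = rng.random(57)
        part = partition_intervals(scores, 5)
        counts = np.zeros(len(scores))
        for k in range(1, part.n + 1):
            counts[part.members(k)] += 1
        assert np.all(counts == 1)

    def test_all_equal_scores_collapse_with_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            part = partition_intervals(np.full(10, 3.0), 4)
        assert part.n == 1
        assert np.all(part.assignment == 1)

    def test_top_interval_holds_top_scores(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=200)
        part = partition_intervals(scores, 4)
        assert scores[part.members(1)].min() > scores[part.members(2)].max()

    def test_rejects_empty_or_single_interval_request(self):
        with pytest.raises(ValueError, match="empty"):
            partition_intervals(np.array([]), 4)
        with pytest.raises(ValueError, match="at least 2"):
            partition_intervals(np.arange(5.0), 1)


class TestEtaMap:
    def test_deterministic_linear_map_n5(self):
        eps = eta_sequence(5, 0.5, 0.1, delta=0.0)
        assert np.allclose(eps, [0.5, 0.4, 0.3, 0.2, 0.1])

    def test_top_interval_gets_eps_max(self):
        assert eta_map(1, 4, delta=0.0) == pytest.approx(0.5)
        assert eta_map(4, 4, delta=0.0) == pytest.approx(0.1)

    def test_strict_monotonicity_across_seeds(self):
        spacing = (0.5 - 0.1) / 3
        for seed in range(50):
            eps = eta_sequence(4, 0.5, 0.1, delta=0.4 * spacing,
                               rng=np.random.default_rng(seed))
            assert np.all(np.diff(eps) < 0)
            assert eps.max() <= 0.5 and eps.min() >= 0.1

    def test_oversized_perturbation_rejected(self):
        spacing = (0.5 - 0.1) / 3
        with pytest.raises(ValueError, match="monotonicity"):
            eta_sequence(4, 0.5, 0.1, delta=0.6 * spacing)

    def test_index_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            eta_map(0, 4)


class TestAllocateBudgets:
    def scores(self, seed=0):
        rng = np.random.default_rng(seed)
        return {m: rng.random(30) for m in ("mRNA", "miRNA", "CNV")}

    def test_equal_modality_shares_summing_to_global(self):
        alloc = allocate_budgets(self.scores(), AllocationConfig())
        for m, groups in alloc.group_epsilons.items():
            assert sum(groups.values()) == pytest.approx(0.8 / 3, abs=1e-12)
        total = sum(sum(g.values()) for g in alloc.group_epsilons.values())
        assert total == pytest.approx(0.8, abs=1e-9)

    def test_identical_relevance_gives_identical_allocations(self):
        rng = np.random.default_rng(1)
        s = rng.random(40)
        alloc = allocate_budgets({m: s.copy() for m in ("mRNA", "miRNA", "CNV")},
                                 AllocationConfig(delta=0.0))
        g = list(alloc.group_epsilons.values())
        assert g[0] == g[1] == g[2]

    def test_uniform_mode_equalises_groups(self):
        alloc = allocate_budgets(self.scores(), AllocationConfig(uniform=True))
        for groups in alloc.group_epsilons.values():
            vals = list(groups.values())
            assert np.allclose(vals, vals[0])

    def test_higher_interval_means_lower_noise_scale(self):
        alloc = allocate_budgets(self.scores(), AllocationConfig(delta=0.0))
        scales = [alloc.noise_scale("mRNA", f"T{k}", 1.0, 256)
                  for k in range(1, 5)]
        assert np.all(np.diff(scales) > 0)      # T_1 least noisy

    def test_missing_modality_rejected(self):
        with pytest.raises(ValueError, match="missing relevance"):
            allocate_budgets({"mRNA": np.arange(5.0)}, AllocationConfig())


class TestClipping:
    def test_large_gradient_rescaled_to_bound(self):
        g = np.full(10, 1.0)                     # L1 norm 10
        clipped = clip_per_sample_gradient(g, 1.0)
        assert np.abs(clipped).sum() == pytest.approx(1.0)

    def test_small_gradient_unchanged(self):
        g = np.array([0.2, -0.3])
        assert np.array_equal(clip_per_sample_gradient(g, 1.0), g)

    def test_direction_preserved(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=20)
        clipped = clip_per_sample_gradient(g, 0.5)
        cos = g @ clipped / (np.linalg.norm(g) * np.linalg.norm(clipped))
        assert cos == pytest.approx(1.0)

    def test_nonpositive_bound_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            clip_per_sample_gradient(np.ones(3), 0.0)


class TestLaplaceSample:
    def test_seeded_determinism(self):
        a = laplace_sample(1.0, (100,), 7)
        b = laplace_sample(1.0, (100,), 7)
        assert np.array_equal(a, b)

    def test_sample_mean_near_zero(self):
        draws = laplace_sample(1.0, (100_000,), 0)
        assert abs(draws.mean()) < 0.02

    def test_distribution_matches_closed_form_cdf(self):
        draws = laplace_sample(0.7, (100_000,), 1)
        p = sps.kstest(draws, sps.laplace(scale=0.7).cdf).pvalue
        assert p > 0.01

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            laplace_sample(0.0, (3,), 0)


class TestAccountant:
    def fill(self, ledger, steps, eps_per_group):
        for step in range(steps):
            for m in ("mRNA", "miRNA", "CNV"):
                for g, e in eps_per_group.items():
                    ledger.record(step, m, g, e, 0.1)

    def test_three_modalities_compose_to_global_budget(self):
        ledger = PrivacyLedger()
        self.fill(ledger, steps=4, eps_per_group={"T1": 0.8 / 6, "deep": 0.8 / 6})
        rep = accountant_report(ledger, global_epsilon=0.8)
        assert rep["per_period_total"] == pytest.approx(0.8, abs=1e-12)
        assert rep["within_budget"]

    def test_empty_ledger_totals_zero(self):
        rep = accountant_report(PrivacyLedger())
        assert rep["per_period_total"] == 0.0
        assert rep["naive_across_training"] == 0.0

    def test_doubling_steps_doubles_naive_composition(self):
        l1, l2 = PrivacyLedger(), PrivacyLedger()
        self.fill(l1, steps=3, eps_per_group={"T1": 0.1})
        self.fill(l2, steps=6, eps_per_group={"T1": 0.1})
        r1, r2 = accountant_report(l1), accountant_report(l2)
        assert r2["naive_across_training"] == pytest.approx(
            2 * r1["naive_across_training"])
        assert r2["per_period_total"] == pytest.approx(r1["per_period_total"])
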