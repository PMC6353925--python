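import math

import numpy as np
import pytest

from multihit.core import (
    Combination,
    ConfusionCounts,
    GreedyConfig,
    combination_weight,
    confusion_counts,
    covers_by_name,
    enumerate_candidates,
    exhaustive_best_step,
    greedy_cover,
    greedy_complexity,
    search_space_size,
)

from conftest import make_cohort


class TestCovers:
    def test_subset_and_missing_gene(self, five_sample_cohort):
        matrix, _ = five_sample_cohort
        assert covers_by_name(matrix, "t1", ("A", "B"))
        assert not covers_by_name(matrix, "t2", ("A", "B"))  # has A only
        with pytest.raises(KeyError, match="Z"):
            covers_by_name(matrix, "t1", ("A", "Z"))

    def test_empty_combination_rejected(self, five_sample_cohort):
        matrix, _ = five_sample_cohort
        from multihit.core import covers
        with pytest.raises(ValueError):
            covers(matrix.sample_row("t1"), np.array([], dtype=np.intp))


class TestConfusionCounts:
    def test_five_sample_enumeration(self, five_sample_cohort):
        # tumors t1:{A,B}, t2:{A}, t3:{B}; normals n1:{A,B}, n2:{}
        matrix, labels = five_sample_cohort
        c = confusion_counts(("A", "B"), matrix, labels)
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 2, 1, 1)
        assert c.total == matrix.n_samples

    def test_nothing_covered(self):
        m2, l2 = make_cohort({"t1": {"A"}, "t2": {"B"}, "n1": {"C"}})
        c = confusion_counts(("A", "B"), m2, l2)
        assert (c.TP, c.FP, c.FN, c.TN) == (0, 0, 2, 1)

    def test_everything_covered(self):
        m, l = make_cohort({"t1": {"A", "B"}, "t2": {"A", "B"},
                            "n1": {"A", "B"}})
        c = confusion_counts(("A", "B"), m, l)
        assert (c.TP, c.FP, c.FN, c.TN) == (2, 1, 0, 0)

    def test_empty_active_set_is_all_zero(self, five_sample_cohort):
        matrix, labels = five_sample_cohort
        c = confusion_counts(("A", "B"), matrix, labels, active=[])
        assert (c.TP, c.FP, c.TN, c.FN) == (0, 0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=0)


class TestCombinationWeight:
    def test_printed_formula(self):
        w = combination_weight(ConfusionCounts(10, 0, 10, 0), 0.1, 10, 10)
        assert w == pytest.approx(20 / 11, abs=1e-4)  # 1.8182

    def test_perfect_combination_at_alpha_one(self):
        w = combination_weight(ConfusionCounts(7, 0, 5, 0), 1.0, 7, 5)
        assert w == 1.0

    def test_zero_denominator_is_infinite(self):
        w = combination_weight(ConfusionCounts(0, 3, 0, 2), 0.1, 2, 3)
        assert math.isinf(w)

    def test_finite_weight_lower_bound(self):
        # for alpha <= 1 any finite weight >= (N_t+N_n)/(alpha*N_t+N_n) >= 1
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_t, n_n = rng.integers(1, 30, size=2)
            TP = int(rng.integers(0, n_t + 1))
            TN = int(rng.integers(0, n_n + 1))
            alpha = float(rng.random())
            c = ConfusionCounts(TP, n_n - TN, TN, n_t - TP)
            w = combination_weight(c, alpha, int(n_t), int(n_n))
            if math.isfinite(w):
                assert w >= (n_t + n_n) / (alpha * n_t + n_n) - 1e-12
                assert w >= 1.0


class TestEnumerateCandidates:
    def test_all_pairs_lexicographic(self):
        m, l = make_cohort({"t1": {"a", "b", "c", "d"}})
        cands = list(enumerate_candidates(m, l, h=2))
        assert cands == [("a", "b"), ("a", "c"), ("a", "d"),
                         ("b", "c"), ("b", "d"), ("c", "d")]

    def test_gene_without_tumor_mutation_pruned(self):
        m, l = make_cohort({"t1": {"a", "b"}, "n1": {"a", "z"}})
        cands = list(enumerate_candidates(m, l, h=2))
        assert cands == [("a", "b")]  # no tuple containing z

    def test_h_larger_than_gene_count_is_empty(self):
        m, l = make_cohort({"t1": {"a", "b"}})
        assert list(enumerate_candidates(m, l, h=3)) == []


class TestSearchSpaceSize:
    def test_small_exact(self):
        assert search_space_size(4, 2) == 6

    def test_genome_scale_magnitudes(self):
        M = search_space_size(20000, 8)
        assert round(M / 10 ** 29) == 6
        NM = greedy_complexity(200, 20000, 2)
        assert round(NM / 10 ** 10) == 4

    def test_precondition(self):
        with pytest.raises(ValueError):
            search_space_size(3, 4)


def replay_active(matrix, labels, solution, config):
    """Replay greedy's active-set evolution, yielding (active, combo)."""
    from multihit.core import coverage_vector
    active = [s for s in matrix.samples if s not in set(solution.uncoverable)]
    for combo in solution.combinations:
        yield list(active), combo
        cov = coverage_vector(matrix, combo.genes)
        idx = matrix.sample_indices(active)
        covered = {s for s, c in zip(active, cov[idx]) if c}
        retire = {s for s in covered
                  if labels.is_tumor(s) or config.exclude_covered_normals}
        active = [s for s in active if s not in retire]


class TestGreedyCover:
    def test_single_perfect_combination(self):
        m, l = make_cohort({"t1": {"g1", "g2"}, "t2": {"g1", "g2"},
                            "n1": set(), "n2": set()})
        sol = greedy_cover(m, l)
        assert sol.gene_tuples == [("g1", "g2")]
        assert len(sol.trace) == 1

    def test_zero_tumor_samples(self):
        m, l = make_cohort({"n1": {"a", "b"}, "n2": {"a"}})
        sol = greedy_cover(m, l)
        assert sol.combinations == [] and sol.trace == []

    def test_two_iteration_fixture_matches_exhaustive_scoring(self):
        # 6 tumors, 3 normals, 6 genes; needs two combinations
        m, l = make_cohort({
            "t1": {"a", "b"}, "t2": {"a", "b"}, "t3": {"a", "b", "e"},
            "t4": {"c", "d"}, "t5": {"c", "d", "f"}, "t6": {"c", "d"},
            "n1": {"a", "c"}, "n2": {"b", "d"}, "n3": {"e", "f"},
        })
        config = GreedyConfig()
        sol = greedy_cover(m, l, config)
        assert len(sol.combinations) == 2
        assert set(sol.gene_tuples) == {("a", "b"), ("c", "d")}
        for active, combo in replay_active(m, l, sol, config):
            oracle = exhaustive_best_step(m, l, active, config)
            assert oracle.genes == combo.genes
            assert oracle.weight == pytest.approx(combo.weight)

    def test_per_step_optimality_on_random_instances(self, random_instance):
        config = GreedyConfig()
        for seed in range(20):
            m, l = random_instance(seed)
            sol = greedy_cover(m, l, config)
            assert not sol.uncoverable
            for active, combo in replay_active(m, l, sol, config):
                oracle = exhaustive_best_step(m, l, active, config)
                assert oracle.genes == combo.genes, f"seed {seed}"
                assert oracle.weight == pytest.approx(combo.weight)

    def test_training_coverage_is_total(self, random_instance):
        from multihit.core import coverage_vector
        for seed in (3, 11):
            m, l = random_instance(seed, n_genes=12, n_t=15, n_n=10)
            sol = greedy_cover(m, l)
            covered = np.zeros(m.n_samples, dtype=bool)
            for combo in sol.combinations:
                covered |= coverage_vector(m, combo.genes)
            tumors = m.sample_indices(l.tumors())
            assert covered[tumors].all()
            assert len(sol.combinations) <= l.n_tumor  # termination bound

    def test_order_invariance(self, random_instance):
        rng = np.random.default_rng(99)
        m, l = random_instance(5)
        sol = greedy_cover(m, l)
        perm_s = rng.permutation(m.n_samples)
        perm_g = rng.permutation(m.n_genes)
        from multihit.cohort import MutationMatrix
        m2 = MutationMatrix([m.samples[i] for i in perm_s],
                            [m.genes[j] for j in perm_g],
                            m.data[np.ix_(perm_s, perm_g)])
        sol2 = greedy_cover(m2, l)
        assert sol.gene_tuples == sol2.gene_tuples

    def test_uncoverable_tumor_reported_not_looped(self):
        m, l = make_cohort({"t1": {"a", "b"}, "t2": {"a"},  # t2 has 1 gene < h
                            "n1": set()})
        sol = greedy_cover(m, l, GreedyConfig(h=2))
        assert sol.uncoverable == ["t2"]
        assert sol.gene_tuples == [("a", "b")]

    def test_normals_kept_when_exclusion_disabled(self):
        m, l = make_cohort({
            "t1": {"a", "b"}, "t2": {"c", "d"},
            "n1": {"a", "b", "c", "d"},
        })
        keep = greedy_cover(m, l, GreedyConfig(exclude_covered_normals=False))
        # with the normal retained, the second iteration still sees FP=1
        assert keep.trace[1]["active_normals"] == 1
        drop = greedy_cover(m, l, GreedyConfig(exclude_covered_normals=True))
        assert drop.trace[1]["active_normals"] == 0


class TestExhaustiveBestStep:
    def test_single_candidate(self):
        m, l = make_cohort({"t1": {"a", "b"}, "n1": set()})
        best = exhaustive_best_step(m, l, m.samples, GreedyConfig())
        assert best.genes == ("a", "b")
        assert best.covered_tumors == frozenset({"t1"})

    def test_all_infinite_weights_is_error(self):
        # alpha=0 and the only normal is covered: denominator 0 everywhere
        m, l = make_cohort({"t1": {"a", "b"}, "n1": {"a", "b"}})
        with pytest.raises(ValueError, match="no usable candidate"):
            exhaustive_best_step(m, l, m.samples, GreedyConfig(alpha=0.0))

    def test_cap_refusal(self, random_instance):
        m, l = random_instance(0)
        with pytest.raises(ValueError, match="cap"):
            exhaustive_best_step(m, l, m.samples, GreedyConfig(oracle_cap=1))


class TestPlantedRecovery:
    def test_noise_free_disjoint_pairs_recovered_exactly(self):
        from multihit.synthetic import PlantedModel, planted_combinations, simulate_cohort
        model = PlantedModel(p_bg=0.0, p_multi=0.0, seed=42)
        matrix, labels, truth = simulate_cohort(model)
        planted = {c for combos in truth.values() for c in combos}
        sol = greedy_cover(matrix, labels)
        assert set(sol.gene_tuples) == planted
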