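"""Reserve-selection GA: fitness components, operators, convergence, oracles."""

import dataclasses

import numpy as np
import pytest

from islereserve.optimizer import (
    NULL_FITNESS,
    FitnessWeights,
    GAConfig,
    ProblemSpec,
    Solution,
    connectivity_score,
    evaluate_fitness,
    exhaustive_maximum_coverage,
    exhaustive_minimum_set,
    ga_optimize,
    greedy_baseline,
    representation,
    spatial_crossover,
    spatial_mutation,
)

from .conftest import binary, full_area, random_minset_instance


def solution_from(vals) -> Solution:
    return Solution(protection=binary(vals))


class TestFitnessComponents:
    def spec(self, **kw):
        area = full_area(4, 4)
        vals = np.zeros((4, 4))
        vals[0, :] = 1.0
        vals[1, :] = 1.0  # 8-cell range
        return ProblemSpec(species_layers={"sp": binary(vals)}, study_area=area, **kw)

    def test_representation_extremes_and_half(self):
        spec = self.spec()
        assert representation(solution_from(np.ones((4, 4))), spec)["sp"] == 1.0
        assert representation(solution_from(np.zeros((4, 4))), spec)["sp"] == 0.0
        half = np.zeros((4, 4))
        half[0, :] = 1.0  # 4 of the 8 range cells
        assert representation(solution_from(half), spec)["sp"] == 0.5

    def test_connectivity_of_single_cell_and_block(self):
        single = np.zeros((4, 4))
        single[1, 1] = 1.0
        assert connectivity_score(solution_from(single)) == 0.0
        block = np.zeros((4, 4))
        block[1:3, 1:3] = 1.0  # 4 rook pairs among 4 cells
        assert connectivity_score(solution_from(block)) == pytest.approx(0.5)
        apart = np.zeros((4, 4))
        apart[0, 0] = apart[3, 3] = 1.0
        assert connectivity_score(solution_from(apart)) == 0.0

    def test_minimum_set_cost_monotonicity(self):
        spec = self.spec(target=0.5)
        cheap = np.zeros((4, 4))
        cheap[0, :] = 1.0  # cost 4, meets 0.5 of 8
        dear = cheap.copy()
        dear[3, :2] = 1.0  # cost 6, same representation
        f_cheap = evaluate_fitness(solution_from(cheap), spec)
        f_dear = evaluate_fitness(solution_from(dear), spec)
        assert f_cheap.feasible and f_dear.feasible
        assert f_cheap.fitness > f_dear.fitness

    def test_missed_target_gets_null_sentinel(self):
        spec = self.spec(target=0.9)
        f = evaluate_fitness(solution_from(np.zeros((4, 4))), spec)
        assert not f.feasible and f.fitness == NULL_FITNESS

    def test_maximum_coverage_saturation(self):
        spec = dataclasses.replace(
            self.spec(target=0.5), formulation="maximum_coverage", budget=16,
            fitness_weights=FitnessWeights(w_repr=1.0, w_cost=1.0, w_conn=0.0),
        )
        f = evaluate_fitness(solution_from(np.ones((4, 4))), spec)
        assert f.feasible and f.fitness == pytest.approx(1.0)

    def test_over_budget_is_infeasible(self):
        spec = dataclasses.replace(self.spec(), formulation="maximum_coverage", budget=2)
        f = evaluate_fitness(solution_from(np.ones((4, 4))), spec)
        assert not f.feasible and f.fitness == NULL_FITNESS

    def test_weighted_targets_scale_and_clamp(self):
        area = full_area(3, 3)
        layers = {"a": binary(np.ones((3, 3))), "b": binary(np.ones((3, 3)))}
        spec = ProblemSpec(species_layers=layers, study_area=area, target=0.5,
                           weights={"a": 3.0, "b": 1.0})
        targets = dict(zip(spec.species_ids, spec.species_targets()))
        assert targets["a"] == pytest.approx(min(1.0, 0.5 * 3.0 / 2.0))
        assert targets["b"] == pytest.approx(0.5 / 2.0)


class TestOperators:
    def test_crossover_identical_parents_fixed_point(self):
        spec = random_minset_instance(0)
        rng = np.random.default_rng(1)
        s = solution_from((np.random.default_rng(2).random((5, 5)) < 0.5).astype(float))
        o1, o2 = spatial_crossover(s, s, spec, rng)
        assert np.array_equal(o1.protection.values, s.protection.values)
        assert np.array_equal(o2.protection.values, s.protection.values)

    def test_crossover_seed_reproducible(self):
        spec = random_minset_instance(0)
        a = solution_from((np.random.default_rng(3).random((5, 5)) < 0.5).astype(float))
        b = solution_from((np.random.default_rng(4).random((5, 5)) < 0.5).astype(float))
        o1 = spatial_crossover(a, b, spec, np.random.default_rng(9))
        o2 = spatial_crossover(a, b, spec, np.random.default_rng(9))
        assert np.array_equal(o1[0].protection.values, o2[0].protection.values)

    def test_crossover_offspring_union_of_parent_cells(self):
        spec = random_minset_instance(0)
        rng = np.random.default_rng(5)
        a = solution_from(np.ones((5, 5)))
        b = solution_from(np.zeros((5, 5)))
        o1, o2 = spatial_crossover(a, b, spec, rng)
        # every cell still comes from one parent, and totals are conserved
        assert o1.cost + o2.cost == a.cost + b.cost

    def test_mutation_disabled_at_rate_zero(self):
        spec = random_minset_instance(0)
        s = solution_from((np.random.default_rng(6).random((5, 5)) < 0.5).astype(float))
        cfg = GAConfig.test_scale(mutation_rate=0.0)
        out = spatial_mutation(s, spec, cfg, np.random.default_rng(0))
        assert np.array_equal(out.protection.values, s.protection.values)

    def test_mutation_full_bias_adopts_neighbour_majority(self):
        spec = random_minset_instance(0, nrows=3, ncols=3)
        ring = np.ones((3, 3))
        ring[1, 1] = 0.0  # every cell's rook neighbourhood is majority-protected
        cfg = GAConfig.test_scale(mutation_rate=100.0, neighborhood_bias=1.0)
        out = spatial_mutation(solution_from(ring), spec, cfg, np.random.default_rng(2))
        assert out.cost >= 8  # either untouched ring or centre filled in

    def test_mutation_seed_reproducible(self):
        spec = random_minset_instance(1)
        s = solution_from((np.random.default_rng(7).random((5, 5)) < 0.5).astype(float))
        cfg = GAConfig.test_scale(mutation_rate=100.0)
        o1 = spatial_mutation(s, spec, cfg, np.random.default_rng(3))
        o2 = spatial_mutation(s, spec, cfg, np.random.default_rng(3))
        assert np.array_equal(o1.protection.values, o2.protection.values)


class TestExhaustiveOracle:
    def test_single_cell_species_is_forced(self):
        area = full_area(3, 3)
        vals = np.zeros((3, 3))
        vals[1, 2] = 1.0
        spec = ProblemSpec(species_layers={"sp": binary(vals)}, study_area=area, target=1.0)
        sol = exhaustive_minimum_set(spec)
        assert sol.cost == 1 and sol.protection.values[1, 2] == 1.0

    def test_disjoint_full_targets_cost_adds(self):
        area = full_area(3, 3)
        a = np.zeros((3, 3)); a[0, :2] = 1.0
        b = np.zeros((3, 3)); b[2, :3] = 1.0
        spec = ProblemSpec(species_layers={"a": binary(a), "b": binary(b)},
                           study_area=area, target=1.0)
        assert exhaustive_minimum_set(spec).cost == 5

    def test_shared_cell_exploited(self):
        # two species sharing one cell; target 0.5 of 2-cell ranges -> one shared cell
        area = full_area(3, 3)
        a = np.zeros((3, 3)); a[0, 0] = a[1, 1] = 1.0
        b = np.zeros((3, 3)); b[1, 1] = b[2, 2] = 1.0
        spec = ProblemSpec(species_layers={"a": binary(a), "b": binary(b)},
                           study_area=area, target=0.5)
        sol = exhaustive_minimum_set(spec)
        assert sol.cost == 1 and sol.protection.values[1, 1] == 1.0

    def test_guard_on_large_instances(self):
        spec = random_minset_instance(0, nrows=6, ncols=6)
        with pytest.raises(ValueError, match="25 cells"):
            exhaustive_minimum_set(spec)


class TestGreedy:
    def test_single_species_greedy_matches_exhaustive(self):
        for seed in range(5):
            spec = random_minset_instance(seed, n_species=1, target=0.6)
            assert greedy_baseline(spec).cost == exhaustive_minimum_set(spec).cost

    def test_empty_budget_gives_empty_solution(self):
        spec = random_minset_instance(
            0, formulation="maximum_coverage", budget=0, target=0.5
        )
        assert greedy_baseline(spec).cost == 0

    def test_greedy_solution_is_feasible_for_minimum_set(self):
        for seed in range(5):
            sol = greedy_baseline(random_minset_instance(seed))
            assert sol.fitness.feasible


class TestGA:
    def test_same_seed_bit_identical(self):
        spec = random_minset_instance(3)
        cfg = GAConfig.test_scale(seed=5, generations=100)
        s1, s2 = ga_optimize(spec, cfg), ga_optimize(spec, cfg)
        assert np.array_equal(s1.protection.values, s2.protection.values)

    def test_more_generations_never_worse(self):
        spec = random_minset_instance(4)
        short = ga_optimize(spec, GAConfig.test_scale(seed=1, generations=50))
        long = ga_optimize(spec, GAConfig.test_scale(seed=1, generations=400))
        assert long.fitness.fitness >= short.fitness.fitness

    def test_budget_slack_reaches_all_targets(self):
        spec = random_minset_instance(
            5, formulation="maximum_coverage", budget=25, target=0.5
        )
        sol = ga_optimize(spec, GAConfig.test_scale(seed=2, generations=300))
        targets = dict(zip(spec.species_ids, spec.species_targets()))
        assert all(sol.fitness.representation[s] >= targets[s] - 1e-9 for s in targets)

    def test_returned_solution_always_feasible(self):
        for seed in range(5):
            spec = random_minset_instance(10 + seed)
            sol = ga_optimize(spec, GAConfig.test_scale(seed=seed, generations=200))
            assert sol.fitness.feasible

    def test_ga_at_least_matches_greedy(self):
        for seed in range(5):
            spec = random_minset_instance(20 + seed)
            ga = ga_optimize(spec, GAConfig.test_scale(seed=seed, generations=300))
            greedy = greedy_baseline(spec)
            assert ga.fitness.fitness >= evaluate_fitness(greedy, spec).fitness

    def test_empty_range_species_rejected_with_diagnostic(self):
        area = full_area(3, 3)
        layers = {"ghost": binary(np.zeros((3, 3)))}
        spec = ProblemSpec(species_layers=layers, study_area=area, target=0.5)
        with pytest.raises(ValueError, match="ghost"):
            ga_optimize(spec, GAConfig.test_scale(seed=0, generations=10))

    def test_connectivity_weight_weakly_increases_connectivity(self):
        # statistical: across instances, higher w_conn never lowers mean connectivity
        lo, hi = [], []
        for seed in range(6):
            for w, acc in ((0.0, lo), (0.5, hi)):
                spec = random_minset_instance(
                    40 + seed, fitness_weights=FitnessWeights(w_conn=w)
                )
                sol = ga_optimize(spec, GAConfig.test_scale(seed=seed, generations=400))
                acc.append(sol.fitness.connectivity)
        assert np.mean(hi) >= np.mean(lo) - 1e-9

    def test_sie_weight_weakly_increases_sie_representation(self):
        # maximum coverage with a tight budget: upweighting one species
        # should on average raise its share of the protected cells
        plain, weighted = [], []
        for seed in range(6):
            base = random_minset_instance(
                60 + seed, formulation="maximum_coverage", budget=5, target=0.8
            )
            for wts, acc in ((None, plain), ({"sp0": 8.0}, weighted)):
                spec = dataclasses.replace(base, weights=wts)
                sol = ga_optimize(spec, GAConfig.test_scale(seed=seed, generations=400))
                acc.append(sol.fitness.representation["sp0"])
        assert np.mean(weighted) >= np.mean(plain) - 1e-9

    def test_lock_in_mask_always_protected(self):
        spec = random_minset_instance(8)
        lock = np.zeros((5, 5)); lock[0, 0] = 1.0
        spec = dataclasses.replace(spec, lock_in=binary(lock))
        sol = ga_optimize(spec, GAConfig.test_scale(seed=3, generations=100))
        assert sol.protection.values[0, 0] == 1.0

    def test_oracle_equivalence_spot_check(self):
        spec = random_minset_instance(99)
        ex = exhaustive_minimum_set(spec)
        ga = ga_optimize(spec, GAConfig.test_scale(seed=0))
        assert ga.cost == ex.cost

    def test_maximum_coverage_oracle_spot_check(self):
        spec = random_minset_instance(
            98, formulation="maximum_coverage", budget=4, target=0.6
        )
        ex = exhaustive_maximum_coverage(spec)
        ga = ga_optimize(spec, GAConfig.test_scale(seed=0, generations=1000))
        assert ga.fitness.fitness == pytest.approx(ex.fitness.fitness, abs=1e-9)
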