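"""Search algorithms: parent selection, truncation survival, greedy
minimization, budget accounting and reproducibility."""

import numpy as np
import pytest

import evodecoy as ed
from .conftest import random_conformation


def scored(conf, e):
    conf.energy = float(e)
    return conf


def dummy_population(energies, rng, sequence="ACDEF"):
    return [scored(random_conformation(sequence, rng), e) for e in energies]


class TestSelectionProbabilities:
    def test_linear_weighting_worked_example(self):
        # energies [0, 5, 10]: weights (10-E) + 0.01*10 -> [10.1, 5.1, 0.1]
        p = ed.selection_probabilities([0.0, 5.0, 10.0])
        assert p == pytest.approx([10.1 / 15.3, 5.1 / 15.3, 0.1 / 15.3],
                                  abs=1e-4)

    def test_all_equal_energies_give_uniform(self):
        p = ed.selection_probabilities([3.0, 3.0, 3.0, 3.0])
        assert np.allclose(p, 0.25)

    def test_empirical_frequencies_match_law(self, rng):
        energies = [0.0, 5.0, 10.0]
        pop = dummy_population(energies, rng)
        p = ed.selection_probabilities(energies)
        n = 100_000
        idx = rng.choice(3, size=n, p=p)  # same sampling path as select_parent
        counts = np.bincount(idx, minlength=3)
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) <= 3 * sigma)

    def test_select_parent_returns_member(self, rng):
        pop = dummy_population([1.0, 2.0, 3.0], rng)
        assert ed.select_parent(pop, rng) in pop


class TestTruncationSelect:
    def test_order_statistic_example(self, rng):
        parents = dummy_population([1.0, 9.0], rng)
        children = dummy_population([3.0, 5.0], rng)
        out = ed.truncation_select(parents, children, 2)
        assert sorted(c.energy for c in out) == [1.0, 3.0]

    def test_all_children_worse_keeps_parents(self, rng):
        parents = dummy_population([1.0, 2.0, 3.0], rng)
        children = dummy_population([10.0, 11.0], rng)
        assert ed.truncation_select(parents, children, 3) == parents

    def test_matches_sort_oracle_on_random_merges(self, rng):
        for _ in range(50):
            parents = dummy_population(rng.normal(size=100), rng, "ACD")
            children = dummy_population(rng.normal(size=100), rng, "ACD")
            out = ed.truncation_select(parents, children, 100)
            merged = sorted(c.energy for c in parents + children)
            assert sorted(c.energy for c in out) == pytest.approx(merged[:100])

    def test_ties_prefer_parents_stably(self, rng):
        parents = dummy_population([1.0, 1.0], rng)
        children = dummy_population([1.0, 1.0], rng)
        out = ed.truncation_select(parents, children, 2)
        assert out == parents

    def test_unscored_member_rejected(self, rng):
        parents = dummy_population([1.0, 2.0], rng)
        bad = random_conformation("ACDEF", rng)  # no energy
        with pytest.raises(ed.ConfigError, match="unscored"):
            ed.truncation_select(parents, [bad], 2)


class TestGreedyMinimize:
    def test_fixed_point_library_halts_after_exactly_n_proposals(self, rng):
        conf = random_conformation("ACDEFG", rng)
        lib_windows = {w: conf.angles[w - 1:w + 2].reshape(1, 9)
                       for w in range(1, 5)}
        lib = ed.FragmentLibrary(n_residues=6, windows=lib_windows)
        toy = ed.ToyEnergy(np.zeros((6, 3)), counter=ed.BudgetCounter())
        conf.energy = toy.score(conf)
        start_count = toy.counter.eval_count
        out = ed.greedy_minimize(conf, lib, toy, rng)
        assert toy.counter.eval_count - start_count == 6  # n proposals
        assert out.energy == conf.energy

    def test_never_increases_energy_and_strictly_decreasing_accepts(self, rng):
        system = ed.make_toy_system(8, entries_per_window=3, seed=2)
        toy = ed.ToyEnergy(system.target.angles, counter=ed.BudgetCounter())
        start = ed.randomize_conformation(
            ed.extended_conformation(system.sequence), system.library, rng)
        start.energy = toy.score(start)
        out = ed.greedy_minimize(start, system.library, toy, rng)
        assert out.energy <= start.energy

    def test_budget_exhaustion_halts_midsearch(self, rng):
        system = ed.make_toy_system(8, entries_per_window=3, seed=2)
        toy = ed.ToyEnergy(system.target.angles,
                           counter=ed.BudgetCounter(eval_max=5))
        start = ed.randomize_conformation(
            ed.extended_conformation(system.sequence), system.library, rng)
        start.energy = toy.score(start)
        out = ed.greedy_minimize(start, system.library, toy, rng)
        assert toy.counter.eval_count == 5
        assert out.energy <= start.energy

    def test_requires_scored_input(self, rng):
        conf = random_conformation("ACDEF", rng)
        system = ed.make_toy_system(5, entries_per_window=2, seed=0)
        toy = ed.ToyEnergy(system.target.angles)
        with pytest.raises(ed.ConfigError, match="scored"):
            ed.greedy_minimize(conf, system.library, toy, rng)


def toy_run(algorithm, *, n=8, pop_size=6, num_child=3, eval_max=60,
            seed=1, system_seed=5, entries=3):
    system = ed.make_toy_system(n, entries_per_window=entries,
                                seed=system_seed)
    energy = ed.ToyEnergy(system.target.angles,
                          counter=ed.BudgetCounter(eval_max=eval_max))
    config = ed.RunConfig(algorithm=algorithm, pop_size=pop_size,
                          num_child=num_child, eval_max=eval_max, seed=seed,
                          diversity_every=10 ** 9)
    omega, logs = ed.run(system.sequence, system.library, energy, config)
    return system, energy, omega, logs


class TestRunBudget:
    def test_budget_boundary_yields_only_initial_population(self):
        system, energy, omega, logs = toy_run("ea", pop_size=6, eval_max=7)
        # init costs 6; the guard admits a single child before exhausting
        assert energy.counter.eval_count == 7

    def test_eval_max_equal_popsize_yields_zero_generations(self):
        system, energy, omega, logs = toy_run("ea", pop_size=6, eval_max=6)
        assert energy.counter.eval_count == 6
        assert logs[-1].generation == 0
        assert len(omega) == 6  # exactly the initial population

    def test_eval_max_below_popsize_rejected(self):
        with pytest.raises(ed.ConfigError):
            ed.RunConfig(algorithm="ea", pop_size=6, eval_max=5, seed=0)

    def test_hand_traced_guard_semantics(self):
        # pop 4, num_child 2, eval_max 10: init(4) + three generations of
        # 2 children each; the guard stops the loop exactly at 10
        system, energy, omega, logs = toy_run(
            "ea", pop_size=4, num_child=2, eval_max=10)
        assert energy.counter.eval_count == 10
        assert logs[-1].generation == 3
        assert len(omega) == 4 * (3 + 1)

    def test_counter_matches_instrumented_oracle_ea_and_mea(self):
        for algo in ("ea", "mea"):
            system = ed.make_toy_system(8, entries_per_window=3, seed=5)
            counter = ed.BudgetCounter(eval_max=300)
            toy = ed.ToyEnergy(system.target.angles, counter=counter)
            calls = {"n": 0}
            orig = toy._breakdown

            def instrumented(conf):
                calls["n"] += 1
                return orig(conf)

            toy._breakdown = instrumented
            config = ed.RunConfig(algorithm=algo, pop_size=6, num_child=3,
                                  eval_max=300, seed=2,
                                  diversity_every=10 ** 9)
            ed.run(system.sequence, system.library, toy, config)
            assert counter.eval_count == calls["n"]
            assert counter.eval_count >= 300  # only stop cause is the budget
            # overshoot bounded by one in-flight evaluation
            assert counter.eval_count - 300 <= 1

    def test_mea_counts_minimization_proposals(self):
        _, energy_ea, omega_ea, logs_ea = toy_run("ea", eval_max=100)
        _, energy_mea, omega_mea, logs_mea = toy_run("mea", eval_max=100)
        # same budget, but MEA spends most of it inside minimization, so
        # it completes far fewer generations
        assert logs_mea[-1].generation < logs_ea[-1].generation


class TestRunInvariants:
    def test_population_size_conserved_and_omega_accounting(self):
        system, energy, omega, logs = toy_run("mea", eval_max=200)
        gens = logs[-1].generation
        assert len(omega) == 6 * (gens + 1)
        per_gen = np.bincount(omega.generations)
        assert np.all(per_gen == 6)

    def test_best_energy_monotone_nonincreasing(self):
        for algo in ("ea", "mea"):
            _, _, _, logs = toy_run(algo, eval_max=400)
            best = [rec.best_energy for rec in logs]
            assert np.all(np.diff(best) <= 1e-12)

    def test_fixed_seed_bit_identical_omega(self):
        for algo in ("ea", "mea"):
            _, _, om1, logs1 = toy_run(algo, eval_max=150)
            _, _, om2, logs2 = toy_run(algo, eval_max=150)
            assert np.array_equal(om1.angles, om2.angles)
            assert np.array_equal(om1.energies, om2.energies)
            assert [r.eval_count for r in logs1] == \
                   [r.eval_count for r in logs2]

    def test_different_seeds_differ(self):
        _, _, om1, _ = toy_run("ea", seed=1, eval_max=150)
        _, _, om2, _ = toy_run("ea", seed=2, eval_max=150)
        assert not np.array_equal(om1.angles, om2.angles)

    def test_initial_population_counts_and_determinism(self, rng):
        system = ed.make_toy_system(8, entries_per_window=2, seed=3)
        toy = ed.ToyEnergy(system.target.angles,
                           counter=ed.BudgetCounter(eval_max=100))
        pop = ed.initial_population(system.sequence, system.library, toy, 5,
                                    np.random.default_rng(7))
        assert toy.counter.eval_count == 5
        pop2 = ed.initial_population(system.sequence, system.library,
                                     ed.ToyEnergy(system.target.angles), 5,
                                     np.random.default_rng(7))
        assert np.array_equal(np.stack([c.angles for c in pop]),
                              np.stack([c.angles for c in pop2]))

    def test_initial_population_budget_shortfall_rejected(self):
        system = ed.make_toy_system(6, entries_per_window=2, seed=3)
        toy = ed.ToyEnergy(system.target.angles,
                           counter=ed.BudgetCounter(eval_max=3))
        with pytest.raises(ed.ConfigError, match="budget"):
            ed.initial_population(system.sequence, system.library, toy, 5,
                                  np.random.default_rng(0))


class TestRunConfig:
    def test_algorithm_defaults_for_num_child(self):
        assert ed.RunConfig(algorithm="ea", seed=0).num_child == 4000
        assert ed.RunConfig(algorithm="mea", seed=0).num_child == 250

    def test_invalid_configs_rejected(self):
        with pytest.raises(ed.ConfigError):
            ed.RunConfig(algorithm="annealing", seed=0)
        with pytest.raises(ed.ConfigError):
            ed.RunConfig(algorithm="ea", pop_size=1, seed=0)
        with pytest.raises(ed.ConfigError):
            ed.RunConfig(algorithm="ea", pop_size=10, num_child=0, seed=0)
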