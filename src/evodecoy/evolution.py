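"""Evolutionary and memetic decoy sampling.

Two population-based stochastic searches over the torsional space of a
protein chain, both driven by the fragment-replacement move and bounded
by a fixed budget of energy evaluations rather than a generation count:

* **basic EA** — a generation selects ``num_child`` parents by
  fitness-proportionate ("fitness-proposal") selection with a linear
  weighting that favors low energies, applies one fragment replacement
  to each, scores the children, and merges parents and children by
  truncation selection (the ``pop_size`` lowest energies survive).
* **memetic EA (MEA)** — identical, except every child is additionally
  mapped to a nearby local minimum by a greedy search (fragment
  replacements accepted only on strict energy decrease, halting after n
  consecutive rejections) before competing for survival.  Every greedy
  proposal is an energy evaluation and counts against the same budget.

The population of every generation (the initial one included) is
appended to the running decoy ensemble Omega, which is the algorithm's
output: the goal is a diverse set of low-energy local minima, not the
single global minimum.

All randomness flows from one root seed through four independent
streams (initialization, parent selection, move proposals,
minimization), so runs are bit-reproducible and toggling minimization
does not perturb the other streams.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence

import numpy as np

from .chain_model import Conformation, extended_conformation, IdealGeometry
from .energy import BudgetCounter, EnergyModel
from .fragments import FragmentLibrary, randomize_conformation, replace_fragment
from .ensemble_analysis import DecoyEnsemble, median_pairwise_lrmsd, lrmsds_to_native

DEFAULT_NUM_CHILD = {"ea": 4000, "mea": 250}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of one sampling run.

    Defaults mirror the benchmark setup (population of 1000; 250
    children per generation for MEA, 4000 for the basic EA; a budget of
    10 million energy evaluations).  Desk-scale work should shrink all
    three — see the package documentation.
    """

    algorithm: str = "mea"
    pop_size: int = 1000
    num_child: Optional[int] = None      # None -> algorithm default
    eval_max: int = 10_000_000
    seed: int = 0
    energy_model: str = "amw"
    library_path: Optional[str] = None
    native_path: Optional[str] = None
    # analytics knobs (not part of the search itself)
    diversity_every: int = 1             # log diversity every k generations
    diversity_max_pairs: int = 200

    def __post_init__(self):
        self.algorithm = self.algorithm.lower()
        if self.algorithm not in ("ea", "mea"):
            raise ConfigError(f"algorithm must be 'ea' or 'mea', "
                              f"got {self.algorithm!r}")
        if self.num_child is None:
            self.num_child = DEFAULT_NUM_CHILD[self.algorithm]
        if self.pop_size < 2:
            raise ConfigError("pop_size >= 2 required")
        if self.num_child < 1:
            raise ConfigError("num_child >= 1 required")
        if self.eval_max < self.pop_size:
            raise ConfigError("eval_max must cover the initial population "
                              "(eval_max >= pop_size)")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenerationLog:
    """One record per completed generation."""

    generation: int
    eval_count: int
    best_energy: float
    mean_energy: float
    median_energy: float
    n_children: int
    n_children_survived: int
    diversity: Optional[float] = None
    diversity_exhaustive: Optional[bool] = None
    best_lrmsd_native: Optional[float] = None


def initial_population(sequence: str, lib: FragmentLibrary,
                       energy: EnergyModel, pop_size: int,
                       rng: np.random.Generator,
                       geometry: Optional[IdealGeometry] = None
                       ) -> List[Conformation]:
    """Seed population: ``pop_size`` times, apply n - 2 fragment
    replacements to the extended chain and score the result once."""
    counter = energy.counter
    if counter.eval_max is not None and counter.remaining < pop_size:
        raise ConfigError(
            f"budget ({counter.remaining} evaluations left) cannot score "
            f"an initial population of {pop_size}")
    base = extended_conformation(sequence, geometry)
    population = []
    for k in range(pop_size):
        conf = randomize_conformation(base, lib, rng)
        conf.energy = energy.score(conf)
        conf.generation = 0
        population.append(conf)
    return population


def selection_probabilities(energies: np.ndarray) -> np.ndarray:
    """Linear fitness weighting for parent selection.

    w_i = (E_max - E_i) + 0.01 * (E_max - E_min); an all-equal
    population degrades to the uniform distribution.  The 1% floor keeps
    the worst member selectable.
    """
    e = np.asarray(energies, dtype=float)
    e_max, e_min = e.max(), e.min()
    if e_max == e_min:
        return np.full(len(e), 1.0 / len(e))
    w = (e_max - e) + 0.01 * (e_max - e_min)
    return w / w.sum()


def select_parent(population: Sequence[Conformation],
                  rng: np.random.Generator) -> Conformation:
    """Fitness-proposal selection of one parent (may repeat across calls)."""
    energies = np.array([c.energy for c in population])
    p = selection_probabilities(energies)
    return population[int(rng.choice(len(population), p=p))]


def truncation_select(parents: Sequence[Conformation],
                      children: Sequence[Conformation],
                      pop_size: int) -> List[Conformation]:
    """The ``pop_size`` lowest-energy members of the merged multiset.

    Ties break by stable order with parents preceding children — mild,
    deterministic elitism.
    """
    merged = list(parents) + list(children)
    if len(merged) < pop_size:
        raise ConfigError("merged set smaller than pop_size")
    energies = []
    for c in merged:
        if c.energy is None:
            raise ConfigError("unscored member in truncation selection")
        energies.append(c.energy)
    order = np.argsort(np.asarray(energies), kind="stable")
    return [merged[i] for i in order[:pop_size]]


def greedy_minimize(conf: Conformation, lib: FragmentLibrary,
                    energy: EnergyModel, rng: np.random.Generator
                    ) -> Conformation:
    """Greedy fragment-replacement descent to a nearby local minimum.

    Proposes fragment replacements, accepting only strict energy
    decreases, until n consecutive proposals are rejected (the working
    definition of a local minimum) or the evaluation budget runs out
    mid-search (the best-so-far state is returned).  Every proposal
    costs exactly one evaluation.
    """
    if conf.energy is None:
        raise ConfigError("greedy_minimize requires a scored conformation")
    n = conf.n_residues
    current = conf
    rejections = 0
    counter = energy.counter
    while rejections < n and not counter.exhausted:
        candidate = replace_fragment(current, lib, rng)
        candidate.energy = energy.score(candidate)
        if candidate.energy < current.energy:
            candidate.generation = current.generation
            candidate.parent_id = current.parent_id
            current = candidate
            rejections = 0
        else:
            rejections += 1
    return current


def run(sequence: str, lib: FragmentLibrary, energy: EnergyModel,
        config: RunConfig, native: Optional[Conformation] = None,
        geometry: Optional[IdealGeometry] = None
        ) -> tuple[DecoyEnsemble, List[GenerationLog]]:
    """Execute one EA or MEA run under a fixed evaluation budget.

    Returns the running ensemble Omega (one population block per
    generation, the initial population included) and the per-generation
    logs.  The loop guard is the budget: a generation in progress stops
    proposing children once the counter reaches ``eval_max``; children
    already scored still compete in that generation's truncation.
    """
    counter = energy.counter
    if counter.eval_max is None:
        counter.eval_max = config.eval_max
    ss = np.random.SeedSequence(config.seed)
    init_rng, select_rng, move_rng, minim_rng = (
        np.random.default_rng(s) for s in ss.spawn(4))

    population = initial_population(sequence, lib, energy, config.pop_size,
                                    init_rng, geometry)
    omega = DecoyEnsemble(sequence=sequence,
                          geometry=geometry or IdealGeometry.default())
    omega.add_population(population, generation=0)
    logs: List[GenerationLog] = []
    _log_generation(logs, population, 0, counter, config, 0, 0, native)

    generation = 0
    while not counter.exhausted:
        generation += 1
        energies = np.array([c.energy for c in population])
        probs = selection_probabilities(energies)
        children: List[Conformation] = []
        for _ in range(config.num_child):
            if counter.exhausted:
                break
            parent_idx = int(select_rng.choice(config.pop_size, p=probs))
            child = replace_fragment(population[parent_idx], lib, move_rng)
            child.generation = generation
            child.parent_id = parent_idx
            child.energy = energy.score(child)
            if config.algorithm == "mea":
                child = greedy_minimize(child, lib, energy, minim_rng)
            children.append(child)
        if not children:
            break
        population = truncation_select(population, children, config.pop_size)
        survivors = sum(1 for c in population if c.generation == generation)
        omega.add_population(population, generation=generation)
        _log_generation(logs, population, generation, counter, config,
                        len(children), survivors, native)
    return omega, logs


def _log_generation(logs: List[GenerationLog],
                    population: Sequence[Conformation], generation: int,
                    counter: BudgetCounter, config: RunConfig,
                    n_children: int, n_survived: int,
                    native: Optional[Conformation]) -> None:
    energies = np.array([c.energy for c in population])
    rec = GenerationLog(
        generation=generation,
        eval_count=counter.eval_count,
        best_energy=float(energies.min()),
        mean_energy=float(energies.mean()),
        median_energy=float(np.median(energies)),
        n_children=n_children,
        n_children_survived=n_survived,
    )
    if generation % max(1, config.diversity_every) == 0:
        n_pairs = len(population) * (len(population) - 1) // 2
        rec.diversity = median_pairwise_lrmsd(
            population, max_pairs=config.diversity_max_pairs,
            rng=np.random.default_rng(
                (config.seed * 1_000_003 + generation) % (2 ** 31)))
        rec.diversity_exhaustive = n_pairs <= config.diversity_max_pairs
    if native is not None:
        angles = np.stack([c.angles for c in population])
        tmp = DecoyEnsemble(sequence=population[0].sequence,
                            geometry=population[0].geometry)
        tmp.add_population(population, generation)
        rec.best_lrmsd_native = float(np.min(lrmsds_to_native(tmp, native)))
    logs.append(rec)
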