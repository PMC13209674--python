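"""Discrete genetic algorithm over fixed-length drug-slot chromosomes.

A chromosome holds K slots, each a drug index or the empty sentinel, so
combination sizes from 1 to K emerge naturally. Selection is tournament
(size 3), crossover uniform (slots carry no positional meaning), mutation
replaces a slot with a random drug or the empty sentinel, and one elite is
preserved so the best-so-far composite J is non-increasing across generations.
Fitness is evaluated on the distinct active-drug set and cached per set
within a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .attribution import Combination, ContributionMatrix
from .fitness import (
    CostTable,
    DEFAULT_EPSILON,
    FitnessBreakdown,
    FitnessWeights,
    breakdown_from_contribution,
)
from .ingest import EffectMatrix
from .scenarios import Scenario, vectorize

#: Integer sentinel for an unoccupied slot.
EMPTY_SLOT = -1


@dataclass(frozen=True)
class GAConfig:
    """Search schedule and operator rates."""

    population_size: int = 150
    iterations: int = 10
    crossover_rate: float = 0.9
    mutation_rate: float = 0.2
    max_drugs: int = 6
    runs: int = 10
    seed: int = 0
    tournament_size: int = 3
    elitism: int = 1
    fixed_size: Optional[int] = None  # constrain combinations to exactly this many drugs

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_drugs < 1:
            raise ValueError("max_drugs must be >= 1")
        if self.fixed_size is not None and not (1 <= self.fixed_size <= self.max_drugs):
            raise ValueError("fixed_size must lie in [1, max_drugs]")


@dataclass(frozen=True)
class SolutionRecord:
    """One evaluated combination with its full fitness breakdown."""

    combination: Combination
    breakdown: FitnessBreakdown
    scenario: str
    run_index: int
    cycle_index: int = 0

    @property
    def drug_count(self) -> int:
        return len(self.combination)

    @property
    def drugs(self) -> tuple:
        return tuple(sorted(self.combination.active))


class _Evaluator:
    """Caches per-active-set fitness; proportional attribution on the scenario-
    masked effect submatrix keeps the inner loop vectorized."""

    def __init__(
        self,
        effects: EffectMatrix,
        c: np.ndarray,
        weights: FitnessWeights,
        costs: CostTable | None,
        max_drugs: int,
        epsilon: float = DEFAULT_EPSILON,
    ):
        mask = c != 0
        self.cols = effects.values[mask]  # G' x D
        self.c = c[mask]
        self.drugs = effects.drugs
        self.weights = weights
        self.costs = costs
        self.max_drugs = max_drugs
        self.epsilon = epsilon
        self._cache: dict[frozenset, FitnessBreakdown] = {}

    def breakdown(self, active: frozenset) -> FitnessBreakdown:
        hit = self._cache.get(active)
        if hit is not None:
            return hit
        idx = sorted(active)
        cols = self.cols[:, idx]
        raw = cols.sum(axis=1)
        e = np.clip(raw, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            shares = np.where(raw[:, None] != 0.0, cols / raw[:, None], 0.0)
        contrib = ContributionMatrix(
            genes=tuple(), drugs=tuple(self.drugs[j] for j in idx),
            values=e[:, None] * shares, effect=e, method="proportional",
        )
        out = breakdown_from_contribution(
            self.c, contrib, weights=self.weights, costs=self.costs,
            max_drugs=self.max_drugs, epsilon=self.epsilon,
        )
        self._cache[active] = out
        return out

    def j(self, active: frozenset) -> float:
        return self.breakdown(active).composite_j


def _active_set(chromosome: np.ndarray) -> frozenset:
    return frozenset(int(a) for a in chromosome if a != EMPTY_SLOT)


def initialize_population(
    n_drugs: int, config: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Random population of slot chromosomes; all-empty rows are redrawn."""
    if n_drugs < 1:
        raise ValueError("drug library is empty")
    if config.fixed_size is not None:
        m = config.fixed_size
        if n_drugs < m:
            raise ValueError(f"library of {n_drugs} cannot fill {m} distinct slots")
        pop = np.stack([
            rng.choice(n_drugs, size=m, replace=False)
            for _ in range(config.population_size)
        ])
        return pop.astype(np.int64)
    pop = rng.integers(EMPTY_SLOT, n_drugs, size=(config.population_size, config.max_drugs))
    for i in range(config.population_size):
        while np.all(pop[i] == EMPTY_SLOT):
            pop[i] = rng.integers(EMPTY_SLOT, n_drugs, size=config.max_drugs)
    return pop


def _repair(pop: np.ndarray, n_drugs: int, config: GAConfig, rng: np.random.Generator) -> None:
    """In place: redraw all-empty rows; for fixed-size runs resample duplicate
    alleles so each row keeps exactly fixed_size distinct drugs."""
    if config.fixed_size is not None:
        for i in range(pop.shape[0]):
            row = pop[i]
            seen: set[int] = set()
            for k in range(row.size):
                if int(row[k]) in seen:
                    choices = np.setdiff1d(np.arange(n_drugs), row, assume_unique=False)
                    row[k] = rng.choice(choices)
                seen.add(int(row[k]))
        return
    for i in range(pop.shape[0]):
        while np.all(pop[i] == EMPTY_SLOT):
            pop[i] = rng.integers(EMPTY_SLOT, n_drugs, size=pop.shape[1])


def _tournament(j_values: np.ndarray, size: int, count: int, rng: np.random.Generator) -> np.ndarray:
    contenders = rng.integers(0, j_values.size, size=(count, size))
    return contenders[np.arange(count), np.argmin(j_values[contenders], axis=1)]


def evolve(
    effects: EffectMatrix,
    scenario: Scenario,
    config: GAConfig,
    weights: FitnessWeights | None = None,
    costs: CostTable | None = None,
    cycle_index: int = 0,
    collect_history: bool = False,
):
    """Run the GA ``config.runs`` times; return deduplicatable solution records.

    Each run returns its best chromosome plus the unique solutions of its final
    population. With ``collect_history`` the per-iteration best-so-far J curves
    (one list per run, monotone non-increasing by elitism) are returned as a
    second value.
    """
    weights = weights or FitnessWeights()
    c = vectorize(scenario, effects.genes)
    n_drugs = len(effects.drugs)
    slot_len = config.fixed_size if config.fixed_size is not None else config.max_drugs
    low = 0 if config.fixed_size is not None else EMPTY_SLOT

    records: list[SolutionRecord] = []
    history: list[list[float]] = []
    for run in range(config.runs):
        rng = np.random.default_rng((config.seed + run) % (2**31))
        evaluator = _Evaluator(effects, c, weights, costs, config.max_drugs)
        pop = initialize_population(n_drugs, config, rng)
        j_values = np.array([evaluator.j(_active_set(row)) for row in pop])
        curve: list[float] = []
        best_idx = int(np.argmin(j_values))
        best = (pop[best_idx].copy(), float(j_values[best_idx]))

        for _ in range(config.iterations):
            parents = pop[_tournament(j_values, config.tournament_size,
                                      config.population_size, rng)]
            offspring = parents.copy()
            # uniform crossover on consecutive pairs
            for a in range(0, config.population_size - 1, 2):
                if rng.random() < config.crossover_rate:
                    swap = rng.random(slot_len) < 0.5
                    tmp = offspring[a, swap].copy()
                    offspring[a, swap] = offspring[a + 1, swap]
                    offspring[a + 1, swap] = tmp
            # per-slot mutation to a random drug (or the empty sentinel)
            mutate = rng.random(offspring.shape) < config.mutation_rate
            offspring[mutate] = rng.integers(low, n_drugs, size=int(mutate.sum()))
            _repair(offspring, n_drugs, config, rng)
            # elitism: best-so-far chromosome replaces the first offspring
            if config.elitism > 0:
                offspring[0] = best[0]
            pop = offspring
            j_values = np.array([evaluator.j(_active_set(row)) for row in pop])
            gen_best = int(np.argmin(j_values))
            if j_values[gen_best] < best[1]:
                best = (pop[gen_best].copy(), float(j_values[gen_best]))
            curve.append(best[1])

        history.append(curve)
        seen: set[frozenset] = set()
        final_sets = [_active_set(best[0])] + [_active_set(row) for row in pop]
        for active in final_sets:
            if active in seen or not active:
                continue
            seen.add(active)
            combo = Combination([effects.drugs[j] for j in sorted(active)],
                                max_drugs=config.max_drugs)
            records.append(SolutionRecord(
                combination=combo, breakdown=evaluator.breakdown(active),
                scenario=scenario.name, run_index=run, cycle_index=cycle_index,
            ))
    if collect_history:
        return records, history
    return records


def dedup_solutions(records: Sequence[SolutionRecord]) -> list[SolutionRecord]:
    """Remove duplicate combinations within (scenario, cycle).

    Uniqueness is by unordered active-drug set; the surviving record is the one
    with the lowest composite J (ties broken by run index for determinism).
    """
    best: dict[tuple, SolutionRecord] = {}
    for rec in records:
        key = (rec.scenario, rec.cycle_index, rec.combination.key)
        cur = best.get(key)
        if cur is None or (rec.breakdown.composite_j, rec.run_index) < (
            cur.breakdown.composite_j, cur.run_index
        ):
            best[key] = rec
    return sorted(
        best.values(),
        key=lambda r: (r.scenario, r.cycle_index, r.breakdown.composite_j, r.drugs),
    )
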