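"""Coarse-to-fine cyclic workflow, Pareto filtering and the MAE-only harness.

A cycle screens the drug library (exclusions, costs), runs the GA, and passes
the surviving drugs to the next cycle. The first (coarse) cycle searches the
union of all scenario modules with a raised combination ceiling and drops
drugs that are never credited above the usage threshold in any retained
solution; later cycles search each scenario over the reduced library with the
cost term switched on. Solutions are finally filtered to the Pareto frontier
over (MAE, combination size), and a comparison harness contrasts the full
composite objective with an MAE-only baseline across scenarios and fixed
combination sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .attribution import proportional_attribution
from .fitness import CostTable, DEFAULT_EPSILON, FitnessWeights, usage_count_cost
from .ga import GAConfig, SolutionRecord, dedup_solutions, evolve
from .ingest import EffectMatrix
from .scenarios import Scenario, union_scenario, vectorize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CycleConfig:
    """Schedule of one search cycle."""

    index: int
    population_size: int
    iterations: int
    kappa: float = 0.0
    max_drugs: int = 6
    exclusions: frozenset = frozenset()
    costs: CostTable | None = None


def default_cycles() -> list[CycleConfig]:
    """Reference three-cycle schedule: coarse 500x100 (cost off, ceiling 7),
    then 250x70 and fine 150x10 with the cost term active."""
    return [
        CycleConfig(index=1, population_size=500, iterations=100, kappa=0.0, max_drugs=7),
        CycleConfig(index=2, population_size=250, iterations=70, kappa=1.0, max_drugs=6),
        CycleConfig(index=3, population_size=150, iterations=10, kappa=1.0, max_drugs=6),
    ]


@dataclass(frozen=True)
class ParetoPoint:
    """Best MAE at one combination size on a scenario's (MAE, size) frontier."""

    scenario: str
    drug_count: int
    best_mae: float
    solutions: tuple = ()


def screen_library(
    effects: EffectMatrix,
    exclusions: Iterable[str] = (),
    costs: CostTable | None = None,
) -> tuple[EffectMatrix, CostTable]:
    """Drop excluded drugs from the matrix; attach costs to the survivors."""
    excluded = {e.strip().lower() for e in exclusions}
    keep = [d for d in effects.drugs if d not in excluded]
    if not keep:
        raise ValueError("all drugs excluded by the screening list")
    dropped = len(effects.drugs) - len(keep)
    if dropped:
        logger.info("screen_library: removed %d of %d drugs", dropped, len(effects.drugs))
    reduced = effects.restrict(drugs=keep) if dropped else effects
    costs = costs or CostTable()
    return reduced, CostTable({d: costs.get(d) for d in keep if costs.get(d) != 0.0})


def _used_drugs(
    records: Sequence[SolutionRecord],
    effects: EffectMatrix,
    scenario_mask: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
) -> set[str]:
    """Drugs credited above epsilon in at least one retained solution."""
    used: set[str] = set()
    for rec in records:
        contrib = proportional_attribution(effects, rec.combination)
        phi, _, _ = usage_count_cost(contrib, epsilon=epsilon, gene_mask=scenario_mask)
        used.update(d for d, p in zip(contrib.drugs, phi) if p > epsilon)
    return used


def run_cycles(
    effects: EffectMatrix,
    scenarios: Sequence[Scenario],
    cycle_configs: Sequence[CycleConfig] | None = None,
    weights: FitnessWeights | None = None,
    ga: GAConfig | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> list[SolutionRecord]:
    """Run the multi-cycle search and return all deduplicated records.

    The first cycle searches the union module over the full (screened)
    library; drugs never credited above ``epsilon`` in any of its retained
    solutions are removed before later cycles, which search each scenario
    separately with that cycle's cost weight. The library can only shrink
    across cycles.
    """
    if not cycle_configs:
        raise ValueError("at least one cycle is required")
    weights = weights or FitnessWeights()
    base = ga or GAConfig()
    library = effects
    all_records: list[SolutionRecord] = []

    for step, cycle in enumerate(cycle_configs):
        library, costs = screen_library(library, cycle.exclusions, cycle.costs)
        config = replace(
            base,
            population_size=cycle.population_size,
            iterations=cycle.iterations,
            max_drugs=cycle.max_drugs,
            seed=(base.seed + 7919 * cycle.index) % (2**31),
        )
        cycle_weights = weights.with_kappa(cycle.kappa)
        coarse = step == 0 and len(cycle_configs) > 1 and len(scenarios) > 1
        targets = [union_scenario(scenarios)] if coarse else list(scenarios)

        cycle_records: list[SolutionRecord] = []
        for s_idx, scenario in enumerate(targets):
            run_config = replace(config, seed=(config.seed + 101 * s_idx) % (2**31))
            recs = evolve(library, scenario, run_config, weights=cycle_weights,
                          costs=costs, cycle_index=cycle.index)
            cycle_records.extend(dedup_solutions(recs))
        all_records.extend(cycle_records)

        if coarse:
            mask = vectorize(union_scenario(scenarios), library.genes) != 0
            used = _used_drugs(cycle_records, library, mask, epsilon)
            if used and len(used) < len(library.drugs):
                logger.info("cycle %d: library reduced %d -> %d drugs",
                            cycle.index, len(library.drugs), len(used))
                library = library.restrict(drugs=sorted(used))
    return all_records


def exhaustive_search(
    effects: EffectMatrix,
    scenario: Scenario,
    weights: FitnessWeights | None = None,
    costs: CostTable | None = None,
    max_drugs: int = 3,
) -> SolutionRecord:
    """Global optimum of the composite J by enumerating every drug set of size
    1..max_drugs (practical only on small libraries; used to audit the GA)."""
    import itertools

    from .attribution import Combination
    from .fitness import composite_fitness

    weights = weights or FitnessWeights()
    c = vectorize(scenario, effects.genes)
    best: SolutionRecord | None = None
    for size in range(1, max_drugs + 1):
        for combo_drugs in itertools.combinations(sorted(effects.drugs), size):
            combo = Combination(combo_drugs, max_drugs=max_drugs)
            bd = composite_fitness(c, effects, combo, weights=weights, costs=costs)
            rec = SolutionRecord(combo, bd, scenario.name, run_index=-1)
            if best is None or (bd.composite_j, len(combo), rec.drugs) < (
                best.breakdown.composite_j, best.drug_count, best.drugs
            ):
                best = rec
    assert best is not None
    return best


def pareto_filter(records: Sequence[SolutionRecord]) -> list[ParetoPoint]:
    """Non-dominated (MAE, drug count) frontier for one scenario's records.

    For each combination size the best MAE is taken (ties broken by lower
    composite J, then lexicographic drug ids); a size stays on the frontier
    only if its MAE strictly improves on every smaller size.
    """
    if not records:
        return []
    scenario_names = {r.scenario for r in records}
    if len(scenario_names) > 1:
        raise ValueError("pareto_filter expects records from a single scenario")
    by_count: dict[int, list[SolutionRecord]] = {}
    for rec in records:
        by_count.setdefault(rec.drug_count, []).append(rec)

    frontier: list[ParetoPoint] = []
    best_so_far = np.inf
    for count in sorted(by_count):
        ranked = sorted(
            by_count[count],
            key=lambda r: (r.breakdown.mae, r.breakdown.composite_j, r.drugs),
        )
        best_mae = ranked[0].breakdown.mae
        if best_mae < best_so_far - 1e-12:
            ties = tuple(r for r in ranked if r.breakdown.mae <= best_mae + 1e-12)
            frontier.append(ParetoPoint(ranked[0].scenario, count, best_mae, ties))
            best_so_far = best_mae
    return frontier


def compare_mae_only(
    effects: EffectMatrix,
    scenarios: Sequence[Scenario],
    config: GAConfig | None = None,
    weights: FitnessWeights | None = None,
    costs: CostTable | None = None,
    sizes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Full composite objective vs MAE-only baseline per (scenario, size) cell.

    Both searches run under identical conditions (schedule, seeds, fixed
    combination size); each cell reports the best MAE found by each objective
    and the outcome for the full objective: ``lower``, ``equal`` or ``higher``.
    """
    config = config or GAConfig()
    weights = weights or FitnessWeights()
    sizes = list(sizes) if sizes is not None else list(range(1, config.max_drugs + 1))
    rows = []
    for s_idx, scenario in enumerate(scenarios):
        for size in sizes:
            cell_cfg = replace(
                config, fixed_size=size,
                seed=(config.seed + 101 * s_idx + 17 * size) % (2**31),
            )
            full = dedup_solutions(evolve(effects, scenario, cell_cfg,
                                          weights=weights, costs=costs))
            base = dedup_solutions(evolve(effects, scenario, cell_cfg,
                                          weights=FitnessWeights.mae_only(), costs=costs))
            mae_full = min(r.breakdown.mae for r in full if r.drug_count == size)
            mae_base = min(r.breakdown.mae for r in base if r.drug_count == size)
            if mae_full < mae_base - 1e-9:
                outcome = "lower"
            elif mae_full > mae_base + 1e-9:
                outcome = "higher"
            else:
                outcome = "equal"
            rows.append({
                "scenario": scenario.name, "drug_count": size,
                "mae_full": mae_full, "mae_baseline": mae_base, "outcome": outcome,
            })
    return pd.DataFrame(rows)
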