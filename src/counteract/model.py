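"""Model/Results surface for combination search.

`CombinationOptimizer` binds an effect matrix to one scenario (plus weights,
costs and the attribution scheme); `fit()` runs the genetic-algorithm search
and returns a `CombinationResults` holding the deduplicated solutions, the
Pareto frontier over (MAE, combination size), convergence history and a
printable summary. `fit_cycles()` runs the coarse-to-fine multi-cycle pipeline
across several scenarios.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .attribution import shapley_attribution
from .fitness import CostTable, FitnessWeights
from .ga import GAConfig, SolutionRecord, dedup_solutions, evolve
from .ingest import EffectMatrix, build_effect_matrix, parse_interactions
from .pipeline import CycleConfig, ParetoPoint, pareto_filter, run_cycles, screen_library
from .scenarios import Scenario, vectorize


class CombinationOptimizer:
    """Search model for drug combinations counteracting one gene module.

    Parameters
    ----------
    effects
        Signed drug-gene effect matrix (genes x drugs).
    scenario
        Gene module with desired directions; its genes must intersect the
        matrix genes.
    weights, costs
        Composite-fitness weights and optional per-drug costs.

    Examples
    --------
    >>> model = CombinationOptimizer(effects, scenario)
    >>> res = model.fit(GAConfig(population_size=100, iterations=20, seed=1))
    >>> print(res.summary())
    """

    def __init__(
        self,
        effects: EffectMatrix,
        scenario: Scenario,
        weights: FitnessWeights | None = None,
        costs: CostTable | None = None,
        exclusions: Sequence[str] = (),
    ):
        self.effects, self.costs = screen_library(effects, exclusions, costs)
        self.scenario = scenario
        self.weights = weights or FitnessWeights()
        # validates the overlap eagerly
        self.counteraction = vectorize(scenario, self.effects.genes)

    @classmethod
    def from_interactions(
        cls,
        path,
        scenario: Scenario,
        weights: FitnessWeights | None = None,
        costs: CostTable | None = None,
        min_evidence: int = 1,
        ambiguity_threshold: float = 0.2,
        **parse_kwargs,
    ) -> "CombinationOptimizer":
        """Build the model straight from a CTD-style interaction file."""
        records = parse_interactions(path, **parse_kwargs)
        effects = build_effect_matrix(
            records, min_evidence=min_evidence, ambiguity_threshold=ambiguity_threshold
        )
        return cls(effects, scenario, weights=weights, costs=costs)

    def fit(self, config: GAConfig | None = None) -> "CombinationResults":
        """Run the GA and return the fitted results."""
        config = config or GAConfig()
        records, history = evolve(
            self.effects, self.scenario, config, weights=self.weights,
            costs=self.costs, collect_history=True,
        )
        return CombinationResults(self, dedup_solutions(records), config, history)

    def fit_cycles(
        self,
        scenarios: Sequence[Scenario],
        cycle_configs: Sequence[CycleConfig] | None = None,
        ga: GAConfig | None = None,
    ) -> list[SolutionRecord]:
        """Coarse-to-fine multi-cycle search across several scenarios."""
        from .pipeline import default_cycles

        return run_cycles(
            self.effects, scenarios, cycle_configs or default_cycles(),
            weights=self.weights, ga=ga,
        )


class CombinationResults:
    """Fitted combination-search results with diagnostics."""

    def __init__(
        self,
        model: CombinationOptimizer,
        records: list[SolutionRecord],
        config: GAConfig,
        history: list[list[float]],
    ):
        self.model = model
        self.records = records
        self.config = config
        self.history = history

    @property
    def best(self) -> SolutionRecord:
        return min(
            self.records,
            key=lambda r: (r.breakdown.composite_j, r.drug_count, r.drugs),
        )

    @property
    def pareto(self) -> list[ParetoPoint]:
        return pareto_filter(self.records)

    def solutions_frame(self) -> pd.DataFrame:
        """All deduplicated solutions, one row per combination."""
        rows = []
        for rec in self.records:
            row = {"scenario": rec.scenario, "cycle": rec.cycle_index,
                   "run": rec.run_index, "drugs": " + ".join(rec.drugs),
                   "drug_count": rec.drug_count}
            row.update(rec.breakdown.as_dict())
            rows.append(row)
        return pd.DataFrame(rows).sort_values("composite_j").reset_index(drop=True)

    def audit_shapley(self, record: SolutionRecord | None = None) -> pd.DataFrame:
        """Exact Shapley attribution of the (best) solution, scenario genes only."""
        record = record or self.best
        contrib = shapley_attribution(self.model.effects, record.combination, mode="exact")
        frame = contrib.to_frame()
        mask = self.model.counteraction != 0
        return frame.loc[np.asarray(self.model.effects.genes)[mask]]

    def plot_convergence(self, ax=None):
        """Best-so-far composite J per iteration, one curve per GA run."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for run, curve in enumerate(self.history):
            ax.plot(range(1, len(curve) + 1), curve, label=f"run {run}")
        ax.set_xlabel("iteration")
        ax.set_ylabel("best composite J")
        ax.set_title(f"Convergence — {self.model.scenario.name}")
        return ax

    def summary(self) -> str:
        """Printable summary: model setup, best solution, Pareto frontier."""
        model = self.model
        best = self.best
        lines = [
            "Combination search results",
            "=" * 60,
            f"Scenario:        {model.scenario.name}"
            + (f" ({model.scenario.description})" if model.scenario.description else ""),
            f"Gene targets:    {len(model.scenario)} "
            f"({sum(1 for d in model.scenario.targets.values() if d < 0)} down, "
            f"{sum(1 for d in model.scenario.targets.values() if d > 0)} up)",
            f"Drug library:    {len(model.effects.drugs)} drugs, "
            f"{len(model.effects.genes)} genes",
            f"GA schedule:     pop {self.config.population_size} x "
            f"{self.config.iterations} iters, {self.config.runs} runs, "
            f"K={self.config.max_drugs}, seed={self.config.seed}",
            f"Unique solutions: {len(self.records)}",
            "-" * 60,
            f"Best combination: {' + '.join(best.drugs)}",
            f"  MAE={best.breakdown.mae:.4f}  J={best.breakdown.composite_j:.4f}  "
            f"coverage={best.breakdown.coverage:.3f}",
            "-" * 60,
            "Pareto frontier (MAE vs combination size):",
            f"{'size':>6} {'best MAE':>10}  drugs",
        ]
        for point in self.pareto:
            drugs = " + ".join(point.solutions[0].drugs) if point.solutions else ""
            lines.append(f"{point.drug_count:>6} {point.best_mae:>10.4f}  {drugs}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<CombinationResults: {len(self.records)} solutions, "
                f"best J={self.best.breakdown.composite_j:.4f}>")
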