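"""Synthetic CTD-like fixtures: interaction files, scenarios, planted optima.

The generator emits delimited interaction tables whose per-pair report counts
reproduce a known ground-truth effect matrix exactly under the regulation-bias
resolution (round-trip exactness), including pairs with deliberately
conflicting direction reports. It can also plant a drug combination that
exactly counteracts a scenario and certify by exhaustive enumeration that it
is the unique minimum-size zero-error solution, surrounded by decoy drugs
(null players, opposing, overshooting and partial-effect columns) chosen to
stress individual fitness terms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ingest import DOWN_LABELS, UP_LABELS, DEFAULT_COLUMNS, EffectMatrix
from .scenarios import Scenario, vectorize

#: Report counts per direction are capped here so every emitted bias sits on a
#: small exactly-representable grid.
MAX_REPORTS = 9

_UP = sorted(UP_LABELS)
_DOWN = sorted(DOWN_LABELS)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and difficulty of a synthetic CTD-like fixture.

    ``conflict_rate`` is the fraction of nonzero drug-gene pairs that receive
    opposing direction reports (|bias| < 1); ``density`` the fraction of
    nonzero cells. ``decoys`` maps decoy kind (null, opposing, overshoot,
    partial) to a count for planted-optimum libraries.
    """

    n_genes: int = 12
    n_drugs: int = 8
    density: float = 0.4
    conflict_rate: float = 0.3
    min_bias: float = 0.2
    seed: int = 0
    n_scenario_genes: int = 6
    planted_size: int = 2
    max_drugs: int = 3
    decoys: Mapping[str, int] = field(
        default_factory=lambda: {"null": 1, "opposing": 2, "overshoot": 2, "partial": 3}
    )
    n_malformed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.conflict_rate <= 1 and 0 <= self.density <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.planted_size < 1 or self.planted_size > self.max_drugs:
            raise ValueError("planted_size must lie in [1, max_drugs]")


def _bias_grid(min_bias: float) -> dict[float, tuple[int, int]]:
    """Exactly representable biases -> minimal (up, down) report counts.

    Only biases of magnitude >= min_bias (or exactly 0) are kept so generated
    cells survive the conservative ambiguity drop unchanged.
    """
    grid: dict[Fraction, tuple[int, int]] = {}
    for up in range(MAX_REPORTS + 1):
        for down in range(MAX_REPORTS + 1):
            total = up + down
            if total == 0:
                continue
            frac = Fraction(up - down, total)
            if frac != 0 and abs(frac) < Fraction(min_bias).limit_denominator(10**6):
                continue
            if frac not in grid or total < sum(grid[frac]):
                grid[frac] = (up, down)
    # key by the float the ingestion-side division produces, for exact round-trips
    return {(c[0] - c[1]) / (c[0] + c[1]): c for c in grid.values()}


_GRID_CACHE: dict[float, dict[float, tuple[int, int]]] = {}


def bias_grid(min_bias: float = 0.2) -> dict[float, tuple[int, int]]:
    if min_bias not in _GRID_CACHE:
        _GRID_CACHE[min_bias] = _bias_grid(min_bias)
    return _GRID_CACHE[min_bias]


def snap_bias(value: float, min_bias: float = 0.2) -> float:
    """Nearest exactly representable bias (ties toward larger magnitude)."""
    grid = bias_grid(min_bias)
    return min(grid, key=lambda b: (abs(b - value), -abs(b)))


def reports_for_bias(value: float, min_bias: float = 0.2) -> tuple[int, int]:
    """Minimal (up, down) report counts reproducing the bias exactly."""
    grid = bias_grid(min_bias)
    if value not in grid:
        raise ValueError(f"bias {value} is not on the representable grid")
    return grid[value]


def random_effect_matrix(spec: FixtureSpec, rng: np.random.Generator | None = None) -> EffectMatrix:
    """Random grid-valued ground-truth matrix with the requested density and
    conflict profile (conflicting pairs get fractional |bias| < 1)."""
    rng = rng or np.random.default_rng(spec.seed)
    genes = [f"G{i+1:03d}" for i in range(spec.n_genes)]
    drugs = [f"drug{j+1:02d}" for j in range(spec.n_drugs)]
    fractional = sorted(b for b in bias_grid(spec.min_bias) if 0 < abs(b) < 1)
    values = np.zeros((spec.n_genes, spec.n_drugs))
    for g in range(spec.n_genes):
        for j in range(spec.n_drugs):
            if rng.random() >= spec.density:
                continue
            sign = 1.0 if rng.random() < 0.5 else -1.0
            if fractional and rng.random() < spec.conflict_rate:
                values[g, j] = sign * abs(rng.choice(fractional))
            else:
                values[g, j] = sign
    return EffectMatrix(genes, drugs, values)


def interactions_from_matrix(
    effects: EffectMatrix,
    path: str | Path,
    rng: np.random.Generator | None = None,
    min_bias: float = 0.2,
    n_malformed: int = 0,
) -> Path:
    """Serialize a grid-valued effect matrix as a CTD-style interaction table.

    Each nonzero cell becomes one report row per supporting reference, with
    direction labels cycled through the label taxonomy; the file round-trips
    through ingestion to the ground truth exactly.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    cols = DEFAULT_COLUMNS
    for g, gene in enumerate(effects.genes):
        for j, drug in enumerate(effects.drugs):
            value = effects.values[g, j]
            if value == 0.0:
                continue
            up, down = reports_for_bias(value, min_bias)
            for r in range(up):
                rows.append((drug, gene, _UP[int(rng.integers(len(_UP)))], 1))
            for r in range(down):
                rows.append((drug, gene, _DOWN[int(rng.integers(len(_DOWN)))], 1))
    for _ in range(n_malformed):
        rows.append(("badrow", "", _UP[0], 1))  # missing gene symbol -> skipped
    order = rng.permutation(len(rows))
    frame = pd.DataFrame(
        [rows[i] for i in order],
        columns=[cols["drug"], cols["gene"], cols["action"], cols["evidence"]],
    )
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def generate_interaction_file(
    spec: FixtureSpec, path: str | Path
) -> tuple[Path, EffectMatrix]:
    """Random ground-truth matrix plus the interaction file that reproduces it."""
    rng = np.random.default_rng(spec.seed)
    truth = random_effect_matrix(spec, rng)
    out = interactions_from_matrix(truth, path, rng, spec.min_bias, spec.n_malformed)
    return out, truth


def _mae_zero_sets(
    effects: EffectMatrix, scenario: Scenario, max_drugs: int
) -> list[frozenset]:
    """All drug sets of size <= max_drugs whose clipped sum matches the
    counteraction vector exactly on scenario genes (generation-time certifier)."""
    c = vectorize(scenario, effects.genes)
    mask = c != 0
    target = c[mask]
    sub = effects.values[mask]
    hits = []
    for size in range(1, max_drugs + 1):
        for combo in itertools.combinations(range(len(effects.drugs)), size):
            e = np.clip(sub[:, combo].sum(axis=1), -1.0, 1.0)
            if np.max(np.abs(e - target)) < 1e-12:
                hits.append(frozenset(effects.drugs[j] for j in combo))
    return hits


def generate_planted_scenario(
    spec: FixtureSpec, max_retries: int = 50
) -> tuple[Scenario, EffectMatrix, tuple]:
    """Scenario + drug library with a certified unique planted optimum.

    The planted drugs partition the scenario genes and each contributes the
    full desired direction on its share, so their sum equals the counteraction
    vector exactly. Decoy columns are then drawn (null, opposing, overshoot,
    partial) and the library is certified by exhaustive enumeration: the
    planted set is the only zero-error set at its size, and every larger
    zero-error set contains it (null players and clipped overshoot may ride
    along). Failing certification redraws the decoys.
    """
    rng = np.random.default_rng(spec.seed)
    n_s = spec.n_scenario_genes
    genes = [f"G{i+1:03d}" for i in range(max(spec.n_genes, n_s))]
    directions = {genes[i]: int(rng.choice([-1, 1])) for i in range(n_s)}
    scenario = Scenario("planted", directions)
    c_full = np.array([directions.get(g, 0) for g in genes], dtype=float)

    planted = [f"plant{p+1}" for p in range(spec.planted_size)]
    share = np.array_split(np.arange(n_s), spec.planted_size)
    decoy_names = [
        f"{kind}{i+1}"
        for kind, count in sorted(spec.decoys.items())
        for i in range(count)
    ]
    drugs = planted + decoy_names

    for attempt in range(max_retries):
        values = np.zeros((len(genes), len(drugs)))
        for p, rows in enumerate(share):
            values[rows, p] = c_full[rows]
        col = spec.planted_size
        for kind, count in sorted(spec.decoys.items()):
            for _ in range(count):
                scope = rng.choice(n_s, size=max(1, n_s // 2), replace=False)
                if kind == "null":
                    pass  # all-zero column
                elif kind == "opposing":
                    values[scope, col] = -c_full[scope]
                elif kind == "overshoot":
                    values[scope, col] = c_full[scope]
                elif kind == "partial":
                    values[scope, col] = 0.5 * c_full[scope]
                else:
                    raise ValueError(f"unknown decoy kind {kind!r}")
                col += 1
        effects = EffectMatrix(genes, drugs, values)
        zero_sets = _mae_zero_sets(effects, scenario, spec.max_drugs)
        planted_set = frozenset(planted)
        minimal = [s for s in zero_sets if len(s) <= spec.planted_size]
        if minimal == [planted_set] and all(planted_set <= s for s in zero_sets):
            return scenario, effects, tuple(planted)
    raise RuntimeError(
        f"could not certify a unique planted optimum after {max_retries} retries"
    )


def write_workspace(directory: str | Path, spec: FixtureSpec | None = None) -> dict:
    """Write a complete demo workspace: interactions, scenarios, costs, config."""
    spec = spec or FixtureSpec()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scenario, effects, planted = generate_planted_scenario(spec)
    rng = np.random.default_rng(spec.seed + 1)
    interactions = interactions_from_matrix(
        effects, directory / "interactions.tsv", rng, spec.min_bias, spec.n_malformed
    )
    scenario_path = directory / "scenarios.yaml"
    scenario_path.write_text(yaml.safe_dump(
        {"scenarios": [{"name": scenario.name, "targets": dict(scenario.targets)}]},
        sort_keys=False,
    ))
    costs_path = directory / "costs.tsv"
    costs_path.write_text("".join(f"{d}\t0.0\n" for d in effects.drugs))
    config_path = directory / "config.yaml"
    config_path.write_text(yaml.safe_dump({
        "interactions": str(interactions),
        "scenarios": str(scenario_path),
        "costs": str(costs_path),
        "seed": spec.seed,
        "ga": {"population_size": 60, "iterations": 20, "runs": 3,
               "max_drugs": spec.max_drugs},
    }, sort_keys=False))
    return {
        "interactions": interactions, "scenarios": scenario_path,
        "costs": costs_path, "config": config_path,
        "scenario": scenario, "effects": effects, "planted": planted,
    }
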