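"""Counteraction scenarios: gene modules with desired regulation directions.

A scenario names a dysregulated gene module and the desired direction of
therapeutic change per gene: -1 to suppress an activated oncogenic signal, +1
to restore a depleted protective function. Ten built-in LUAD driver scenarios
ship as packaged data; their union (the coarse "Scenario 11" search space)
covers 44 unique genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

UNION_NAME = "Scenario 11"


@dataclass(frozen=True)
class Scenario:
    """A named gene module with desired counteraction directions (exactly ±1)."""

    name: str
    targets: Mapping[str, int]
    description: str = ""

    def __post_init__(self) -> None:
        cleaned = {}
        for gene, direction in self.targets.items():
            gene = gene.strip().upper()
            if int(direction) not in (-1, 1):
                raise ValueError(f"{self.name}: direction for {gene} must be ±1, got {direction}")
            if gene in cleaned:
                raise ValueError(f"{self.name}: duplicate gene {gene}")
            cleaned[gene] = int(direction)
        if not cleaned:
            raise ValueError(f"{self.name}: scenario needs at least one target gene")
        object.__setattr__(self, "targets", cleaned)

    @property
    def genes(self) -> list[str]:
        return list(self.targets)

    def __len__(self) -> int:
        return len(self.targets)


def builtin_scenarios() -> list[Scenario]:
    """The ten packaged LUAD driver scenarios."""
    text = resources.files("counteract.data").joinpath("luad_scenarios.yaml").read_text()
    raw = yaml.safe_load(text)
    return [
        Scenario(entry["name"], entry["targets"], entry.get("axis", ""))
        for entry in raw["scenarios"]
    ]


def load_scenarios(path: str | Path) -> list[Scenario]:
    """Load scenarios from a YAML/JSON file mapping name -> {gene: ±1}.

    Accepts either the packaged list form (``scenarios: [{name, targets}, ...]``)
    or a flat mapping ``{name: {gene: ±1}, ...}``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if isinstance(raw, Mapping) and "scenarios" in raw:
        return [
            Scenario(e["name"], e["targets"], e.get("axis", "")) for e in raw["scenarios"]
        ]
    if isinstance(raw, Mapping):
        return [Scenario(name, targets) for name, targets in raw.items()]
    raise ValueError(f"unrecognized scenario file structure in {path}")


def union_scenario(scenarios: Sequence[Scenario], name: str = UNION_NAME) -> Scenario:
    """Union of scenarios into one coarse-search module.

    Genes shared between scenarios must carry a consistent desired direction;
    a conflict is a fatal error naming the gene.
    """
    merged: dict[str, int] = {}
    for scenario in scenarios:
        for gene, direction in scenario.targets.items():
            if gene in merged and merged[gene] != direction:
                raise ValueError(
                    f"conflicting desired direction for {gene}: "
                    f"{merged[gene]:+d} vs {direction:+d} (in {scenario.name})"
                )
            merged[gene] = direction
    return Scenario(name, merged, "union of all scenario modules")


def vectorize(scenario: Scenario, genes: Sequence[str]) -> np.ndarray:
    """Counteraction vector c over an ordered gene universe.

    c[g] is the scenario's desired direction for gene g and 0 for genes outside
    the scenario. Scenario genes missing from the universe are dropped with a
    warning; zero overlap is fatal (nothing to optimize).
    """
    index = {g.upper(): i for i, g in enumerate(genes)}
    c = np.zeros(len(genes))
    missing = []
    for gene, direction in scenario.targets.items():
        if gene in index:
            c[index[gene]] = direction
        else:
            missing.append(gene)
    if missing:
        logger.warning(
            "%s: %d scenario gene(s) absent from gene universe: %s",
            scenario.name, len(missing), ", ".join(sorted(missing)),
        )
    if not np.any(c):
        raise ValueError(f"{scenario.name}: no scenario gene present in the gene universe")
    return c
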