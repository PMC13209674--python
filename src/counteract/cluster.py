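"""Hierarchical clustering of regulation effects and grouped-alternatives tables.

Genes and drugs are clustered by their signed effect profiles so that
interchangeable compounds (similar regulation patterns across a scenario's
genes) surface as groups of alternatives, and gene clusters sharing the same
directional support can be read off a heatmap-ready reordered matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .ga import SolutionRecord
from .ingest import EffectMatrix
from .scenarios import Scenario


@dataclass(frozen=True)
class ClusterEntry:
    """One gene cluster and the drugs offering matching directional support."""

    label: str
    genes: tuple
    directions: tuple  # desired direction per gene, aligned with `genes`
    drugs: tuple


@dataclass(frozen=True)
class ClusterGrouping:
    """Partition of a scenario's genes into sign-pattern clusters with drug
    alternatives; every scenario gene appears in exactly one cluster."""

    scenario: str
    entries: tuple

    def to_frame(self) -> pd.DataFrame:
        """Table 2-style rows: Scenario, Reg, Gene Cluster, Drug Alternatives, Group."""
        rows = []
        for entry in self.entries:
            for reg in (-1, 1):
                genes = [g for g, d in zip(entry.genes, entry.directions) if d == reg]
                if not genes:
                    continue
                rows.append({
                    "Scenario": self.scenario,
                    "Reg": "Down" if reg < 0 else "Up",
                    "Gene Cluster": ", ".join(genes),
                    "Drug Alternatives": ", ".join(entry.drugs),
                    "Group": entry.label,
                })
        return pd.DataFrame(rows)


def _group_labels(n: int) -> list[str]:
    labels = []
    for i in range(n):
        name = ""
        k = i
        while True:
            name = chr(ord("A") + k % 26) + name
            k = k // 26 - 1
            if k < 0:
                break
        labels.append(name)
    return labels


def cluster_effect_matrix(
    effects: EffectMatrix,
    method: str = "average",
    metric: str = "euclidean",
) -> dict:
    """Agglomerative clustering of both axes of the effect matrix.

    Rows/columns are canonically pre-sorted by label so the result is invariant
    to input order. Returns leaf orderings (label lists) and the merge
    (linkage) matrices; a degenerate axis (single row or column) gets the
    identity ordering and no dendrogram.
    """
    ordered = effects.restrict(genes=sorted(effects.genes), drugs=sorted(effects.drugs))
    out: dict = {"genes": list(ordered.genes), "drugs": list(ordered.drugs)}
    for axis, labels, data in (
        ("gene", ordered.genes, ordered.values),
        ("drug", ordered.drugs, ordered.values.T),
    ):
        if len(labels) < 2:
            out[f"{axis}_order"] = list(labels)
            out[f"{axis}_linkage"] = None
            continue
        link = linkage(pdist(data, metric=metric), method=method)
        order = leaves_list(link)
        out[f"{axis}_order"] = [labels[i] for i in order]
        out[f"{axis}_linkage"] = link
    return out


def group_alternatives(
    records: Sequence[SolutionRecord],
    effects: EffectMatrix,
    scenario: Scenario,
    tolerance: float = 0.0,
) -> ClusterGrouping:
    """Partition scenario genes by identical directional-support patterns.

    For every drug appearing in the given (typically Pareto-filtered)
    solutions, a gene is "supported" when the drug's signed effect matches the
    gene's desired direction with magnitude above ``tolerance``. Genes with
    identical support patterns form one cluster; the cluster's alternatives are
    exactly the supporting drugs. Group letters run A, B, C, ... by descending
    cluster size, then alphabetically by first gene.
    """
    drugs = sorted({d for rec in records for d in rec.combination.active})
    genes = [g for g in scenario.genes if g in set(effects.genes)]
    patterns: dict[tuple, list[str]] = {}
    for gene in genes:
        gi = effects.gene_index(gene)
        direction = scenario.targets[gene]
        pattern = tuple(
            np.sign(effects.values[gi, effects.drug_index(d)]) == direction
            and abs(effects.values[gi, effects.drug_index(d)]) > tolerance
            for d in drugs
        )
        patterns.setdefault(pattern, []).append(gene)

    clusters = sorted(
        patterns.items(), key=lambda kv: (-len(kv[1]), sorted(kv[1])[0])
    )
    entries = []
    for label, (pattern, members) in zip(_group_labels(len(clusters)), clusters):
        members = sorted(members)
        entries.append(ClusterEntry(
            label=label,
            genes=tuple(members),
            directions=tuple(scenario.targets[g] for g in members),
            drugs=tuple(d for d, hit in zip(drugs, pattern) if hit),
        ))
    return ClusterGrouping(scenario=scenario.name, entries=tuple(entries))
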