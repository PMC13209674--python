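"""Ingestion of CTD-style drug-gene interaction records into a signed effect matrix.

CTD annotates each chemical-gene interaction with a direction-of-effect action
label such as ``increases^expression``. Because evidence is aggregated across
studies, the same drug-gene pair may carry conflicting directions; a
regulation-bias score resolves each pair into a single signed weight in [-1, 1]
from the frequency of reported directions, dropping ambiguous pairs
conservatively.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Action labels treated as upregulation of the gene product.
UP_LABELS = frozenset(
    {
        "increases^expression",
        "increases^stability",
        "increases^abundance",
        "decreases^degradation",
        "decreases^ubiquitination",
    }
)

#: Action labels treated as downregulation of the gene product.
DOWN_LABELS = frozenset(
    {
        "decreases^expression",
        "decreases^stability",
        "increases^degradation",
        "decreases^abundance",
        "increases^ubiquitination",
    }
)

#: Default column names of a CTD-style interaction table.
DEFAULT_COLUMNS = {
    "drug": "ChemicalName",
    "gene": "GeneSymbol",
    "action": "InteractionActions",
    "evidence": "PubMedIDs-count",
}


@dataclass(frozen=True)
class InteractionRecord:
    """One directional drug-gene interaction report.

    ``evidence_count`` is the number of supporting references behind the row
    (CTD's PubMed count); it defaults to 1 so that unannotated rows count as a
    single report.
    """

    drug_id: str
    gene_symbol: str
    action_label: str
    evidence_count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_id", self.drug_id.strip().lower())
        object.__setattr__(self, "gene_symbol", self.gene_symbol.strip().upper())
        if not self.action_label:
            raise ValueError("action_label must be non-empty")
        if self.evidence_count < 1:
            object.__setattr__(self, "evidence_count", 1)


@dataclass(frozen=True)
class DirectionTaxonomy:
    """Partition of action labels into up- and down-regulating sets.

    Labels in neither set are non-directional (e.g. ``affects^binding``) and
    are ignored. The two sets must be disjoint.
    """

    up_labels: frozenset[str] = UP_LABELS
    down_labels: frozenset[str] = DOWN_LABELS

    def __post_init__(self) -> None:
        overlap = set(self.up_labels) & set(self.down_labels)
        if overlap:
            raise ValueError(f"taxonomy sets overlap on {sorted(overlap)}")


def classify_direction(action_label: str, taxonomy: DirectionTaxonomy | None = None) -> int:
    """Map an action label to +1 (up), -1 (down) or 0 (non-directional)."""
    taxonomy = taxonomy or DirectionTaxonomy()
    if action_label in taxonomy.up_labels:
        return 1
    if action_label in taxonomy.down_labels:
        return -1
    return 0


def parse_interactions(
    path: str | Path,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> list[InteractionRecord]:
    """Parse a delimited CTD-style interaction table into records.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    sep
        Field separator; inferred from the extension when None (``.csv`` comma,
        otherwise tab).
    columns
        Mapping with keys ``drug``, ``gene``, ``action`` and optionally
        ``evidence`` naming the corresponding columns; defaults to CTD export
        names.

    Rows with a missing drug, gene or action field are skipped and counted; the
    skip count is logged. An unreadable file or zero parsable rows is fatal.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"cannot read interaction file {path}: {exc}") from exc

    for key in ("drug", "gene", "action"):
        if cols[key] not in frame.columns:
            raise ValueError(f"missing required column {cols[key]!r} in {path}")

    has_evidence = cols.get("evidence") in frame.columns
    drugs = frame[cols["drug"]].tolist()
    genes = frame[cols["gene"]].tolist()
    actions = frame[cols["action"]].tolist()
    evidences = frame[cols["evidence"]].tolist() if has_evidence else [None] * len(frame)
    records: list[InteractionRecord] = []
    skipped = 0
    for drug, gene, action, raw_evidence in zip(drugs, genes, actions, evidences):
        if not _present(drug) or not _present(gene) or not _present(action):
            skipped += 1
            continue
        evidence = 1
        if _present(raw_evidence):
            try:
                evidence = max(1, int(float(raw_evidence)))
            except ValueError:
                evidence = 1
        records.append(InteractionRecord(str(drug), str(gene), str(action).strip(), evidence))

    if skipped:
        logger.info("parse_interactions: skipped %d malformed row(s) in %s", skipped, path)
    if not records:
        raise ValueError(f"no parsable interaction rows in {path}")
    return records


def _present(value: object) -> bool:
    return value is not None and not (isinstance(value, float) and np.isnan(value)) and str(value).strip() != ""


def regulation_bias(
    records: Sequence[InteractionRecord],
    taxonomy: DirectionTaxonomy | None = None,
    min_evidence: int = 1,
    ambiguity_threshold: float = 0.2,
) -> float:
    """Resolve conflicting direction reports for one drug-gene pair.

    Let U and V be the evidence counts of up- and down-classified reports. The
    bias is the bounded ratio (U - V) / (U + V); pairs with U + V below
    ``min_evidence`` or |bias| below ``ambiguity_threshold`` are dropped to 0
    (conservative handling of ambiguous evidence).
    """
    taxonomy = taxonomy or DirectionTaxonomy()
    up = sum(r.evidence_count for r in records if classify_direction(r.action_label, taxonomy) > 0)
    down = sum(r.evidence_count for r in records if classify_direction(r.action_label, taxonomy) < 0)
    total = up + down
    if total == 0 or total < min_evidence:
        return 0.0
    bias = (up - down) / total
    if abs(bias) < ambiguity_threshold:
        return 0.0
    return bias


class EffectMatrix:
    """Signed per-drug per-gene regulation weights r[g, j] in [-1, 1].

    Rows are genes (uppercased symbols), columns drugs (lowercased ids); a cell
    is 0 iff no retained directional evidence exists for that pair.
    """

    def __init__(self, genes: Sequence[str], drugs: Sequence[str], values: np.ndarray):
        genes = list(genes)
        drugs = list(drugs)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(genes), len(drugs)):
            raise ValueError(f"values shape {values.shape} != ({len(genes)}, {len(drugs)})")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene symbols")
        if len(set(drugs)) != len(drugs):
            raise ValueError("duplicate drug ids")
        if np.any(np.abs(values) > 1 + 1e-12):
            raise ValueError("effect weights must lie in [-1, 1]")
        self.genes = genes
        self.drugs = drugs
        self.values = values
        self._gene_index = {g: i for i, g in enumerate(genes)}
        self._drug_index = {d: j for j, d in enumerate(drugs)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene.upper()]

    def drug_index(self, drug: str) -> int:
        try:
            return self._drug_index[drug.lower()]
        except KeyError:
            raise KeyError(f"unknown drug id {drug!r}") from None

    def drug_columns(self, drugs: Iterable[str]) -> np.ndarray:
        """G x k sub-matrix for the given drugs (order preserved)."""
        idx = [self.drug_index(d) for d in drugs]
        return self.values[:, idx]

    def restrict(self, genes: Sequence[str] | None = None, drugs: Sequence[str] | None = None) -> "EffectMatrix":
        gsel = self.genes if genes is None else [g.upper() for g in genes]
        dsel = self.drugs if drugs is None else [d.lower() for d in drugs]
        rows = [self._gene_index[g] for g in gsel]
        cols = [self._drug_index[d] for d in dsel]
        return EffectMatrix(gsel, dsel, self.values[np.ix_(rows, cols)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.drugs)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EffectMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def save(self, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
        """Write a delimited matrix (genes x drugs) plus a JSON sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t")
        sidecar = {"genes": len(self.genes), "drugs": len(self.drugs)}
        if metadata:
            sidecar.update(metadata)
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=list))

    @classmethod
    def load(cls, path: str | Path) -> "EffectMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame)

    def __repr__(self) -> str:
        return f"EffectMatrix({len(self.genes)} genes x {len(self.drugs)} drugs)"


def build_effect_matrix(
    records: Sequence[InteractionRecord],
    taxonomy: DirectionTaxonomy | None = None,
    min_evidence: int = 1,
    ambiguity_threshold: float = 0.2,
    prune_empty: bool = False,
) -> EffectMatrix:
    """Assemble the effect matrix over the union of observed genes and drugs.

    Each cell is the regulation bias of that pair's records. With
    ``prune_empty`` genes and drugs whose entire row/column resolved to zero
    are dropped.
    """
    if not records:
        raise ValueError("no interaction records")
    taxonomy = taxonomy or DirectionTaxonomy()
    pairs: dict[tuple[str, str], list[InteractionRecord]] = {}
    for rec in records:
        pairs.setdefault((rec.gene_symbol, rec.drug_id), []).append(rec)

    genes = sorted({g for g, _ in pairs})
    drugs = sorted({d for _, d in pairs})
    gi = {g: i for i, g in enumerate(genes)}
    di = {d: j for j, d in enumerate(drugs)}
    values = np.zeros((len(genes), len(drugs)))
    for (gene, drug), recs in pairs.items():
        values[gi[gene], di[drug]] = regulation_bias(recs, taxonomy, min_evidence, ambiguity_threshold)

    if prune_empty:
        keep_g = np.abs(values).sum(axis=1) > 0
        keep_d = np.abs(values).sum(axis=0) > 0
        genes = [g for g, k in zip(genes, keep_g) if k]
        drugs = [d for d, k in zip(drugs, keep_d) if k]
        values = values[np.ix_(keep_g, keep_d)]
    return EffectMatrix(genes, drugs, values)
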