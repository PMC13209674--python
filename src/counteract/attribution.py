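"""Net combination effects and per-gene credit attribution across drugs.

A combination's net effect on gene g is the clipped sum of the selected drugs'
signed effects, e_g = clip(sum_k r_{g,k}, -1, 1). Credit for e_g is allocated
across the drugs either proportionally to raw effects (fast, adequate when
clipping is modest) or by the Shapley value of the clipped-sum coalition game
(fair under saturation and redundancy: efficiency, symmetry, null player and
linearity hold). Exact Shapley enumerates all subsets — cheap at combination
sizes up to six or seven — and a Monte-Carlo permutation estimator is provided
for parity with large-scale use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ingest import EffectMatrix

#: Sentinel for an unoccupied chromosome slot.
EMPTY = None


@dataclass(frozen=True)
class Combination:
    """Up to K drug slots; empty slots are None. The evaluated set is the
    ordered distinct non-empty drugs (duplicates collapse: a drug cannot be
    taken twice in a set-based model)."""

    slots: tuple
    max_drugs: int = 6

    def __init__(self, drugs: Sequence[Optional[str]], max_drugs: int = 6):
        slots = tuple(d.lower() if isinstance(d, str) else None for d in drugs)
        if len(slots) > max_drugs:
            raise ValueError(f"{len(slots)} slots exceed K={max_drugs}")
        object.__setattr__(self, "slots", slots)
        object.__setattr__(self, "max_drugs", max_drugs)
        if not self.active:
            raise ValueError("combination must contain at least one drug")

    @property
    def active(self) -> tuple:
        """Distinct non-empty drugs, first-appearance order."""
        seen: dict[str, None] = {}
        for d in self.slots:
            if d is not None and d not in seen:
                seen[d] = None
        return tuple(seen)

    @property
    def key(self) -> frozenset:
        return frozenset(self.active)

    def __len__(self) -> int:
        return len(self.active)

    def __repr__(self) -> str:
        return "Combination(" + " + ".join(self.active) + ")"


@dataclass(frozen=True, eq=False)
class ContributionMatrix:
    """Per-gene, per-drug credited effects a[g, j] for one combination.

    Efficiency holds per gene: sum_j a[g, j] equals the net clipped effect e_g
    (exactly for proportional and exact Shapley; within Monte-Carlo error for
    the permutation estimator).
    """

    genes: tuple
    drugs: tuple
    values: np.ndarray
    effect: np.ndarray
    method: str
    permutations: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes), columns=list(self.drugs))


def combination_effect(effects: EffectMatrix, combo: Combination) -> np.ndarray:
    """Net per-gene effect e_g = clip(sum over selected drugs of r_{g,k}, -1, 1)."""
    cols = effects.drug_columns(combo.active)
    return np.clip(cols.sum(axis=1), -1.0, 1.0)


def proportional_attribution(effects: EffectMatrix, combo: Combination) -> ContributionMatrix:
    """Allocate e_g across drugs proportionally to raw effects.

    a[g, j] = e_g * r[g, j] / S_g with S_g the unclipped sum; all zero when
    S_g = 0 (exactly cancelling evidence credits nobody).
    """
    cols = effects.drug_columns(combo.active)
    raw_sum = cols.sum(axis=1)
    e = np.clip(raw_sum, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        shares = np.where(raw_sum[:, None] != 0.0, cols / raw_sum[:, None], 0.0)
    values = e[:, None] * shares
    return ContributionMatrix(
        genes=tuple(effects.genes), drugs=combo.active, values=values,
        effect=e, method="proportional",
    )


def _subset_masks(k: int) -> np.ndarray:
    """Boolean membership table of all 2^k subsets (rows) over k players."""
    ids = np.arange(2 ** k)
    return (ids[:, None] >> np.arange(k)) & 1 > 0


def shapley_attribution(
    effects: EffectMatrix,
    combo: Combination,
    mode: str = "exact",
    permutations: int = 256,
    seed: int | None = None,
) -> ContributionMatrix:
    """Shapley attribution of the clipped-sum game f_g(T) = clip(sum_{k in T} r_{g,k}).

    ``exact`` enumerates all 2^|S| subsets and applies the Shapley weight
    |T|! (|S|-|T|-1)! / |S|! to each marginal f_g(T ∪ {j}) - f_g(T).
    ``monte_carlo`` averages marginal contributions over uniformly sampled
    drug orderings (one marginal per drug per permutation), seeded.
    """
    drugs = combo.active
    k = len(drugs)
    cols = effects.drug_columns(drugs)  # G x k
    if mode == "exact":
        masks = _subset_masks(k)  # 2^k x k
        subset_vals = np.clip(cols @ masks.T, -1.0, 1.0)  # G x 2^k
        sizes = masks.sum(axis=1)
        values = np.zeros_like(cols)
        fact = np.array([factorial(i) for i in range(k + 1)], dtype=float)
        for j in range(k):
            without = ~masks[:, j]
            t_ids = np.nonzero(without)[0]
            with_ids = t_ids | (1 << j)  # subset index with j added
            w = fact[sizes[t_ids]] * fact[k - sizes[t_ids] - 1] / fact[k]
            values[:, j] = (subset_vals[:, with_ids] - subset_vals[:, t_ids]) @ w
        nperm = 0
    elif mode == "monte_carlo":
        if permutations < 1:
            raise ValueError("permutations must be >= 1")
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((permutations, k)), axis=1)  # P x k uniform orderings
        reordered = cols[:, perms]  # G x P x k
        prefix = np.clip(np.cumsum(reordered, axis=2), -1.0, 1.0)
        marginals = np.diff(prefix, axis=2, prepend=0.0)  # G x P x k, position order
        values = np.zeros_like(cols)
        for j in range(k):
            # average the marginal drug j received at whatever position it held
            pos = np.argmax(perms == j, axis=1)  # P
            values[:, j] = marginals[:, np.arange(permutations), pos].mean(axis=1)
        nperm = permutations
    else:
        raise ValueError(f"unknown Shapley mode {mode!r}")

    e = np.clip(cols.sum(axis=1), -1.0, 1.0)
    return ContributionMatrix(
        genes=tuple(effects.genes), drugs=drugs, values=values,
        effect=e, method="shapley", permutations=nperm,
    )


def attribute(
    effects: EffectMatrix,
    combo: Combination,
    method: str = "proportional",
    permutations: int = 256,
    seed: int | None = None,
) -> ContributionMatrix:
    """Dispatch to the requested attribution scheme."""
    if method == "proportional":
        return proportional_attribution(effects, combo)
    if method == "shapley":
        return shapley_attribution(effects, combo, mode="exact")
    if method == "shapley_mc":
        return shapley_attribution(effects, combo, mode="monte_carlo",
                                   permutations=permutations, seed=seed)
    raise ValueError(f"unknown attribution method {method!r}")
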