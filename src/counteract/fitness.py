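"""Composite fitness: MAE plus contribution-aware penalty and reward terms.

The primary objective is the mean absolute error between the desired
counteraction vector c and the net combination effect e, taken over scenario
genes. Secondary terms are computed from a contribution matrix and shape the
search: a waste penalty for same-direction credit beyond the target magnitude,
a mismatch penalty for credit opposing the target, a per-gene entropy penalty
discouraging diffuse credit, a coverage reward for direction-correct
fulfillment capped at the target, a parsimony count of drugs with credited
usage above a threshold, and an optional signed cost term. The composite is

    J = alpha*MAE + beta*R_waste + gamma*R_mis + eta*R_entropy
        + lambda*R_count + kappa*R_cost - tau*Cov

with secondary terms normalized (waste/mismatch/entropy by scenario gene
count, coverage by the total gene weight, count by the slot budget K) so the
weights act on comparable scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attribution import Combination, ContributionMatrix, attribute
from .ingest import EffectMatrix

#: Credited-usage threshold for the parsimony and cost indicators.
DEFAULT_EPSILON = 1e-9


@dataclass(frozen=True)
class FitnessWeights:
    """Non-negative weights of the composite objective.

    Defaults follow the reference parameterization: MAE dominates (alpha=1),
    waste/mismatch/coverage at 0.2, entropy and drug count at 0.05, cost off
    (kappa=0) for the coarse cycle and 1 afterwards.
    """

    alpha: float = 1.0
    beta: float = 0.2
    gamma: float = 0.2
    eta: float = 0.05
    lambda_count: float = 0.05
    kappa: float = 0.0
    tau: float = 0.2

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "eta", "lambda_count", "kappa", "tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be non-negative")

    @classmethod
    def mae_only(cls) -> "FitnessWeights":
        """Baseline objective: J = MAE, all secondary weights zero."""
        return cls(alpha=1.0, beta=0.0, gamma=0.0, eta=0.0,
                   lambda_count=0.0, kappa=0.0, tau=0.0)

    def with_kappa(self, kappa: float) -> "FitnessWeights":
        return replace(self, kappa=kappa)


class CostTable:
    """Per-drug cost scalars: positive to avoid, negative to prefer, absent = 0."""

    def __init__(self, costs: Mapping[str, float] | None = None):
        self._costs = {str(k).strip().lower(): float(v) for k, v in (costs or {}).items()}
        for drug, cost in self._costs.items():
            if not np.isfinite(cost):
                raise ValueError(f"non-finite cost for {drug!r}")

    def get(self, drug: str) -> float:
        return self._costs.get(drug.lower(), 0.0)

    def vector(self, drugs: Sequence[str]) -> np.ndarray:
        return np.array([self.get(d) for d in drugs])

    def items(self):
        return self._costs.items()

    def __len__(self) -> int:
        return len(self._costs)

    @classmethod
    def from_file(cls, path: str | Path, sep: str | None = None) -> "CostTable":
        """Two-column delimited file: drug_id, cost. Header optional."""
        path = Path(path)
        if sep is None:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
        costs: dict[str, float] = {}
        for _, row in frame.iterrows():
            try:
                costs[str(row.iloc[0])] = float(row.iloc[1])
            except (TypeError, ValueError):
                continue  # header or malformed row
        return cls(costs)


@dataclass(frozen=True)
class FitnessBreakdown:
    """All fitness terms (normalized as used in J) plus the composite."""

    mae: float
    r_waste: float
    r_mismatch: float
    r_entropy: float
    coverage: float
    r_count: float
    r_cost: float
    composite_j: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mae": self.mae, "r_waste": self.r_waste, "r_mismatch": self.r_mismatch,
            "r_entropy": self.r_entropy, "coverage": self.coverage,
            "r_count": self.r_count, "r_cost": self.r_cost, "composite_j": self.composite_j,
        }


def mae(c: np.ndarray, e: np.ndarray, gene_mask: np.ndarray | None = None) -> float:
    """Mean absolute error |c - e| over masked (scenario) genes."""
    c = np.asarray(c, dtype=float)
    e = np.asarray(e, dtype=float)
    if c.shape != e.shape:
        raise ValueError("counteraction and effect vectors differ in length")
    mask = c != 0 if gene_mask is None else np.asarray(gene_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty gene mask for MAE")
    return float(np.abs(c[mask] - e[mask]).mean())


def _same_sign_mass(c: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Per-gene sum of |a_ij| over credits whose sign matches c_i (c_i != 0)."""
    aligned = np.sign(values) == np.sign(c)[:, None]
    return np.where(aligned, np.abs(values), 0.0).sum(axis=1)


def waste_penalty(c: np.ndarray, contrib: ContributionMatrix, normalize: bool = False) -> float:
    """Same-direction credited magnitude in excess of the target |C_i| (overshoot)."""
    c = np.asarray(c, dtype=float)
    mask = c != 0
    excess = np.maximum(0.0, _same_sign_mass(c, contrib.values)[mask] - np.abs(c[mask]))
    total = float(excess.sum())
    return total / mask.sum() if normalize else total


def mismatch_penalty(c: np.ndarray, contrib: ContributionMatrix, normalize: bool = False) -> float:
    """Credited magnitude opposing the target direction (zero credits excluded)."""
    c = np.asarray(c, dtype=float)
    mask = c != 0
    values = contrib.values[mask]
    opposing = (np.sign(values) != 0) & (np.sign(values) != np.sign(c[mask])[:, None])
    total = float(np.where(opposing, np.abs(values), 0.0).sum())
    return total / mask.sum() if normalize else total


def entropy_penalty(c: np.ndarray, contrib: ContributionMatrix, normalize: bool = False) -> float:
    """Sum over genes of the entropy (nats) of same-sign credit shares.

    For each target gene, p_ij is drug j's share of the same-sign credit mass;
    H_i = -sum p log p with 0 log 0 := 0; genes without same-sign mass
    contribute 0.
    """
    c = np.asarray(c, dtype=float)
    mask = c != 0
    values = contrib.values[mask]
    aligned = np.where(np.sign(values) == np.sign(c[mask])[:, None], np.abs(values), 0.0)
    mass = aligned.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(mass > 0, aligned / np.where(mass > 0, mass, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    total = float(-plogp.sum())
    return total / mask.sum() if normalize else total


def coverage_reward(
    c: np.ndarray,
    contrib: ContributionMatrix,
    omega: np.ndarray | None = None,
    normalize: bool = False,
) -> float:
    """Direction-correct fulfillment, capped at each gene's target magnitude.

    Each target gene contributes omega_i * min(|C_i|, same-sign credit mass) /
    |C_i| — at most omega_i, with no reward for overshoot. Normalized form
    divides by the total weight, giving a value in [0, 1].
    """
    c = np.asarray(c, dtype=float)
    mask = c != 0
    if omega is None:
        w = np.ones(int(mask.sum()))
    else:
        omega = np.asarray(omega, dtype=float)
        w = omega[mask] if omega.shape == c.shape else omega
        if np.any(w < 0):
            raise ValueError("gene weights must be non-negative")
    mass = _same_sign_mass(c, contrib.values)[mask]
    terms = w * np.minimum(np.abs(c[mask]), mass) / np.abs(c[mask])
    total = float(terms.sum())
    if normalize:
        wsum = float(w.sum())
        return total / wsum if wsum > 0 else 0.0
    return total


def usage_count_cost(
    contrib: ContributionMatrix,
    costs: CostTable | None = None,
    epsilon: float = DEFAULT_EPSILON,
    gene_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, int, float]:
    """Per-drug credited usage phi_j = sum_i |a_ij|, the active-drug count
    #{j: phi_j > eps} and the summed cost of active drugs."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    values = contrib.values if gene_mask is None else contrib.values[np.asarray(gene_mask, bool)]
    phi = np.abs(values).sum(axis=0)
    active = phi > epsilon
    r_count = int(active.sum())
    cost_vec = (costs or CostTable()).vector(contrib.drugs)
    r_cost = float(cost_vec[active].sum())
    return phi, r_count, r_cost


def composite_fitness(
    c: np.ndarray,
    effects: EffectMatrix,
    combo: Combination,
    weights: FitnessWeights | None = None,
    costs: CostTable | None = None,
    attribution_mode: str = "proportional",
    omega: np.ndarray | None = None,
    epsilon: float = DEFAULT_EPSILON,
    permutations: int = 256,
    seed: int | None = None,
) -> FitnessBreakdown:
    """Evaluate all fitness terms from a single contribution matrix.

    Secondary terms are normalized before weighting: waste, mismatch and
    entropy by the scenario gene count, coverage by the total gene weight
    (giving [0, 1]) and the drug count by the slot budget K; the cost term is
    left on the user's cost scale.
    """
    contrib = attribute(effects, combo, method=attribution_mode,
                        permutations=permutations, seed=seed)
    return breakdown_from_contribution(
        c, contrib, weights=weights, costs=costs, max_drugs=combo.max_drugs,
        omega=omega, epsilon=epsilon,
    )


def breakdown_from_contribution(
    c: np.ndarray,
    contrib: ContributionMatrix,
    weights: FitnessWeights | None = None,
    costs: CostTable | None = None,
    max_drugs: int = 6,
    omega: np.ndarray | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> FitnessBreakdown:
    """Assemble the normalized breakdown and composite J from a precomputed
    contribution matrix (shared by the GA's inner loop and the public API)."""
    weights = weights or FitnessWeights()
    c = np.asarray(c, dtype=float)
    mask = c != 0
    value_mae = mae(c, contrib.effect, mask)
    waste = waste_penalty(c, contrib, normalize=True)
    mismatch = mismatch_penalty(c, contrib, normalize=True)
    entropy = entropy_penalty(c, contrib, normalize=True)
    cov = coverage_reward(c, contrib, omega=omega, normalize=True)
    _, count, cost = usage_count_cost(contrib, costs, epsilon=epsilon, gene_mask=mask)
    count_term = count / max_drugs
    j = (
        weights.alpha * value_mae
        + weights.beta * waste
        + weights.gamma * mismatch
        + weights.eta * entropy
        + weights.lambda_count * count_term
        + weights.kappa * cost
        - weights.tau * cov
    )
    return FitnessBreakdown(
        mae=value_mae, r_waste=waste, r_mismatch=mismatch, r_entropy=entropy,
        coverage=cov, r_count=count_term, r_cost=cost, composite_j=float(j),
    )
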