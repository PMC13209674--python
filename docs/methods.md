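# Methods

## Problem setting

A scenario is a small module of dysregulated genes with a desired direction
of therapeutic change per gene, encoded as a counteraction vector
c ∈ {−1, 0, +1}<sup>G</sup>: −1 for genes whose activated oncogenic signal
should be suppressed, +1 for depleted protective functions to restore, 0 for
genes outside the module. All target magnitudes are ±1; no per-gene weighting
beyond the optional coverage weights ω is applied. Ten LUAD driver modules
(44 unique genes) ship as packaged YAML; overlapping genes carry the same
direction in every module, so their union (the coarse "Scenario 11" search
space) is well defined.

## Effect matrix from interaction records

CTD-style records annotate each drug–gene interaction with an action label.
Five labels are treated as upregulation (`increases^expression`,
`increases^stability`, `increases^abundance`, `decreases^degradation`,
`decreases^ubiquitination`) and five as downregulation (the mirrored list);
all other labels are non-directional and ignored rather than rejected, since
curated interaction data carry many such actions (binding, metabolism, ...).

Conflicting reports for one pair are resolved by the regulation bias
r = (U−V)/(U+V), with U and V the summed evidence counts (references per
row, default 1) of up- and down-classified reports. The ratio is bounded,
sign-preserving and antisymmetric under swapping U and V. Two conservative
drops zero a pair: total evidence below `min_evidence` (default 1) and
|bias| below `ambiguity_threshold` (default 0.2). Both are configuration
knobs, as is whether rows are weighted by their reference count or counted
equally (set every `evidence_count` to 1 for the latter). The signed
magnitude, not just the sign, enters the effect matrix.

## Combination effect and attribution

For a drug set S (duplicates in a chromosome collapse — a drug cannot be
taken twice in a set-based model), the net effect per gene is the clipped
sum ê<sub>g</sub> = clip(Σ<sub>k∈S</sub> r<sub>g,k</sub>, −1, 1). Additivity
up to saturation is the only interaction model; dose, PK/PD and genuine
drug–drug interaction terms are out of scope.

Credit for ê<sub>g</sub> is allocated across drugs by either route:

- **Proportional**: a<sub>g,j</sub> = ê<sub>g</sub> r<sub>g,j</sub> / S<sub>g</sub>
  with S<sub>g</sub> the unclipped sum, and a<sub>g,j</sub> = 0 when
  S<sub>g</sub> = 0 (exact cancellation credits nobody). Fast, used inside
  the search loop; efficiency Σ<sub>j</sub> a<sub>g,j</sub> = ê<sub>g</sub>
  holds identically.
- **Shapley**: the value of the coalition game
  f<sub>g</sub>(T) = clip(Σ<sub>k∈T</sub> r<sub>g,k</sub>, −1, 1). Exact
  computation enumerates all 2<sup>|S|</sup> subsets (at most 128 at the
  coarse-cycle ceiling K = 7), which is cheap enough that the exact route is
  the default audit path for top solutions; a Monte-Carlo estimator
  averaging one marginal per drug per uniformly sampled ordering (default
  256 permutations, seeded) is provided for parity with large-scale use.
  Marginal contributions lie in [−2, 2], so Hoeffding's inequality bounds
  the Monte-Carlo deviation at 256 draws below ≈0.35 with high family-wise
  probability across the fixture sizes we test; the empirically observed
  maximum is reported by the acceptance script (typically < 0.1).

sgn(0) is defined as 0: a zero attribution belongs to neither the same-sign
nor the opposite-sign class in any penalty below.

## Fitness terms

All terms are computed from one contribution matrix, on scenario genes only
(C<sub>i</sub> = 0 genes are excluded everywhere, so off-target genes never
dilute the error — the MAE denominator is the scenario gene count, with the
gene mask exposed for callers who want a fixed universe instead).

- **MAE** (primary): mean |c<sub>g</sub> − ê<sub>g</sub>|; 0 means the
  combination fully matches the counteraction vector.
- **Waste** R<sub>waste</sub> = Σ<sub>i</sub> max(0, m<sub>i</sub> − |C<sub>i</sub>|),
  where m<sub>i</sub> is the same-sign credited magnitude
  Σ<sub>j: sgn a<sub>ij</sub> = sgn C<sub>i</sub></sub> |a<sub>ij</sub>|:
  overshoot in the correct direction, symmetric for up- and downregulation
  because it uses magnitudes.
- **Mismatch** R<sub>mis</sub> = Σ<sub>i</sub> Σ<sub>j: opposing</sub> |a<sub>ij</sub>|:
  credit pushed against the target direction. Absolute values are summed so
  the penalty is non-negative.
- **Entropy** R<sub>entropy</sub> = Σ<sub>i</sub> H<sub>i</sub> with
  H<sub>i</sub> the natural-log entropy of the same-sign credit shares
  p<sub>ij</sub> = |a<sub>ij</sub>| 1[same sign] / m<sub>i</sub>,
  0·log 0 := 0, and H<sub>i</sub> = 0 when m<sub>i</sub> = 0. A single
  contributor gives 0; n equal contributors give ln n.
- **Coverage** Cov = Σ<sub>i</sub> ω<sub>i</sub> min(|C<sub>i</sub>|, m<sub>i</sub>)/|C<sub>i</sub>|:
  direction-correct fulfillment capped at the target, so overshoot earns
  nothing. Default ω<sub>i</sub> = 1. The cap/ratio form is our reading of
  the reward's intent (meet the target magnitude in the correct direction,
  without encouraging overshoot).
- **Parsimony and cost**: credited usage φ<sub>j</sub> = Σ<sub>i</sub> |a<sub>ij</sub>|
  (magnitudes, so opposing credit still counts as usage);
  R<sub>count</sub> = #{j : φ<sub>j</sub> > ε} and
  R<sub>cost</sub> = Σ<sub>j: φ<sub>j</sub> > ε</sub> c<sub>j</sub>, with
  ε = 10⁻⁹ by default. Costs are user-supplied scalars: positive to avoid a
  drug, negative to prefer it (complementary-drug search), absent = 0.

The composite is J = α·MAE + β·R<sub>waste</sub> + γ·R<sub>mis</sub> +
η·R<sub>entropy</sub> + λ·R<sub>count</sub> + κ·R<sub>cost</sub> − τ·Cov.
Before weighting, waste, mismatch and entropy are divided by the scenario
gene count, coverage by Σω (giving [0, 1]) and the drug count by K; the cost
term is left on the user's scale. This normalization scheme is a documented
design choice — the terms must merely be on comparable scales for the
default weights (α = 1, β = γ = τ = 0.2, η = λ = 0.05; κ = 0 in the coarse
cycle, 1 afterwards) to act as intended. With α = 1 and all other weights 0
the composite ranking provably equals the plain MAE ranking, which is the
baseline used by the comparison harness.

## Genetic algorithm

Chromosomes are K slots (K = 6 by default, 7 in the coarse cycle), each a
drug index or an empty sentinel, so combination sizes 1..K emerge without a
separate size gene. Fitness is evaluated on the distinct active-drug set and
cached per set within a run. Operators, chosen as standard defaults for
categorical chromosomes where the search procedure itself leaves them open:
tournament selection of size 3, uniform crossover applied to parent pairs
with probability 0.9 (slots carry no positional meaning), per-slot mutation
with probability 0.2 to a random drug or the empty sentinel, all-empty
chromosomes redrawn, and one elite preserved so the best-so-far J is
monotone non-increasing — the property the convergence logs and tests rely
on. Each of the (default 10) runs uses an rng seeded by base seed + run
index; identical seeds give bit-identical solution lists. The comparison
harness constrains chromosomes to an exact active-slot count (no empty
sentinel; duplicate alleles repaired by resampling) so each grid cell
compares searches at a fixed combination size.

Duplicate combinations are removed within (scenario, cycle) by unordered
drug set, keeping the record with the lowest J.

## Cycles, screening, Pareto filtering

The reference schedule runs three cycles: 500×100 (coarse, κ = 0, ceiling
K = 7), 250×70 and 150×10 (κ = 1). The coarse cycle searches the union
module; drugs whose credited usage never exceeds ε in any retained coarse
solution are dropped — an operational stand-in for the manual vetting a
practitioner would apply between cycles, which is out of scope here.
Exclusion lists (one drug per line) and cost files (drug, cost) express
external screening sources. The library can only shrink across cycles, and
a one-cycle run with no exclusions and zero costs reduces to the plain GA.

Per scenario, solutions are reduced to the Pareto frontier over (MAE,
combination size): best MAE per size (ties broken by lower J, then
lexicographic drug ids), keeping a size only if it strictly improves on all
smaller ones — equal-MAE ties resolve toward fewer drugs.

## Reporting

Genes and drugs are hierarchically clustered on their signed effect profiles
(average linkage, Euclidean distance by default; axes pre-sorted by label so
the result is input-order invariant) for heatmap-style review. Grouped
alternatives partition scenario genes by identical directional-support
patterns across the solution drugs: a drug supports a gene when its signed
effect matches the desired direction (magnitude above a tolerance, default
any nonzero — groupings therefore depend on signs only). Each cluster's
alternatives are exactly its supporting drugs; group letters run A, B, C, …
by descending cluster size, then alphabetically by first gene — the
lettering convention is defined here.

## Synthetic fixtures

The generator emulates the *shape* of curated interaction data: delimited
tables with direction labels from the taxonomy, per-pair report counts
(capped at 9 per direction, so emitted biases sit on an exactly
representable grid and survive ingestion unchanged — round-trip exactness is
asserted), a configurable fraction of pairs with deliberately conflicting
directions, and optional malformed rows to exercise skip handling. Default
fixture sizes (a dozen genes, eight to ten drugs, ~40% density, 30% conflict
rate) keep enumeration oracles exact and tests fast while exercising every
code path; they are far smaller and cleaner than a real curated snapshot.

Planted-optimum libraries split a scenario among `planted_size` drugs whose
effects sum exactly to the counteraction vector, surrounded by decoys chosen
to stress individual fitness terms: null players (parsimony), opposing
columns (mismatch), overshooting columns (waste/clipping) and half-magnitude
partial columns (coverage). Exhaustive enumeration certifies at generation
time that the planted set is the unique zero-error set at its size and that
every larger zero-error set contains it (null players and clipped overshoot
may ride along); failing certification redraws the decoys.

What passing on these fixtures shows: the machinery — resolution,
attribution, fitness algebra, search, filtering — behaves as specified and
recovers known optima. What it does not show: that real, biased, incomplete
interaction snapshots yield biologically valid combinations; direction
labels aggregated across cell types and doses are evidence signals, not
quantitative response measurements, and no dose, toxicity or interaction
pharmacology is modeled.

## Numerical choices and problem sizes

Float comparisons in dominance and dedup use 10⁻¹² slack; the comparison
harness calls outcomes equal within 10⁻⁹. Deterministic tie-breaks
(J, then size, then lexicographic drug ids) make every reported "best"
reproducible. The acceptance script scales simulations to desk size as its
own study design: a 44-gene × 12-drug synthetic matrix at a reduced GA
schedule (30×6, 2 runs) for the 60-cell grid, 1,000 random fixtures for
attribution efficiency (Monte-Carlo deviation sampled every tenth fixture),
100 random 10-drug libraries at K = 3 against the enumeration oracle with
the fine-search schedule (150×10, 10 runs), and one planted fixture for
recovery; the full reference schedules remain the package defaults.

## Known limitations

Clipping is the only non-additivity; costs are static scalars; scenario
directions are binary; the GA offers no global-optimality guarantee (the
enumeration oracle exists precisely to audit it at small scale); and the
coarse-cycle survivor rule is an operational definition, not a
reconstruction of manual curation.
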