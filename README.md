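# counteract

Contribution-aware optimization of small drug combinations against
dysregulated gene modules.

Many computational drug-repurposing methods score candidates by global
signature reversal or network proximity, treating every disease gene as
equally important and optimizing a single scalar. `counteract` instead starts
from an explicit *scenario*: a small module of dysregulated genes, each with a
desired direction of change (−1 to suppress an activated oncogenic signal,
+1 to restore a depleted protective function). Ten curated lung
adenocarcinoma (LUAD) driver scenarios — RTK activation, KRAS–MAPK,
STK11/KEAP1, PI3K/AKT/mTOR, DDR dysfunction, RET/NTRK fusions,
SMARCA4-deficiency and others, 44 unique genes in total — ship as packaged,
editable data; user scenarios load from YAML.

## Model

Direction-aware drug–gene interaction records (CTD-style, with action labels
such as `increases^expression`) are resolved per drug–gene pair into a signed
**regulation bias** r<sub>g,j</sub> = (U−V)/(U+V) ∈ [−1, 1], where U and V
are the evidence counts of up- and down-classified reports; ambiguous pairs
(low total evidence, or |bias| below a threshold) are conservatively zeroed.
A combination S of up to K drugs acts on gene g through the clipped sum
ê<sub>g</sub> = clip(Σ<sub>k∈S</sub> r<sub>g,k</sub>, −1, 1).

The primary fit is the mean absolute error to the counteraction vector c,
MAE = (1/G) Σ<sub>g</sub> |c<sub>g</sub> − ê<sub>g</sub>| over scenario
genes. Each gene's net effect is then *attributed* across the drugs — either
proportionally (a<sub>g,j</sub> = ê<sub>g</sub> r<sub>g,j</sub>/S<sub>g</sub>)
or by the Shapley value of the clipped-sum coalition game (exact subset
enumeration, or Monte-Carlo permutation sampling) — and the attribution
feeds six secondary terms: a waste penalty (same-direction credit beyond
|C<sub>i</sub>|), a mismatch penalty (credit opposing the target), a per-gene
entropy penalty over same-sign credit shares, a coverage reward
min(|C<sub>i</sub>|, same-sign mass)/|C<sub>i</sub>|, a parsimony count of
drugs with credited usage above ε, and an optional signed cost term. The
composite objective

J = α·MAE + β·R<sub>waste</sub> + γ·R<sub>mis</sub> + η·R<sub>entropy</sub> + λ·R<sub>count</sub> + κ·R<sub>cost</sub> − τ·Cov

is minimized by a discrete genetic algorithm (tournament selection, uniform
crossover at rate 0.9, per-slot mutation at rate 0.2, elitism) over
fixed-length chromosomes of drug slots, run repeatedly per scenario, with a
coarse-to-fine multi-cycle pipeline (union "Scenario 11" search, survivor
propagation, cost activation) and Pareto filtering over (MAE, combination
size). Defaults: α=1, β=γ=τ=0.2, η=λ=0.05, K=6, 10 runs, cycle schedules
500×100 / 250×70 / 150×10.

## Worked example

```python
from counteract import CombinationOptimizer, GAConfig
from counteract.synthetic import FixtureSpec, write_workspace

ws = write_workspace("demo", FixtureSpec(seed=0))          # synthetic workspace
model = CombinationOptimizer.from_interactions(ws["interactions"], ws["scenario"])
res = model.fit(GAConfig(population_size=80, iterations=10, runs=3,
                         max_drugs=3, seed=1))
print(res.summary())
```

```
Combination search results
============================================================
Scenario:        planted
Gene targets:    6 (3 down, 3 up)
Drug library:    9 drugs, 6 genes
GA schedule:     pop 80 x 10 iters, 3 runs, K=3, seed=1
Unique solutions: 34
------------------------------------------------------------
Best combination: plant1 + plant2
  MAE=0.0000  J=-0.1667  coverage=1.000
------------------------------------------------------------
Pareto frontier (MAE vs combination size):
  size   best MAE  drugs
     1     0.5000  plant1
     2     0.0000  plant1 + plant2
```

The synthetic workspace plants a two-drug combination that exactly counteracts
a six-gene scenario among decoy drugs. The search recovers it: MAE 0 means the
clipped combined effect matches the counteraction vector on every scenario
gene; coverage 1.0 means every target is fully met in the correct direction;
J < 0 because the coverage reward outweighs the remaining parsimony penalty.
The single best one-drug solution (`plant1`) only covers half the module
(MAE 0.5). `res.audit_shapley()` shows the per-gene credit split — here each
planted drug is solely credited for its own half of the module.

The same workflow runs from the shell:

```bash
counteract fixtures --out demo --seed 0
counteract optimize --config demo/config.yaml --scenario planted \
    --scenarios-file demo/scenarios.yaml --seed 1 --out demo/run
counteract cycles  --interactions demo/interactions.tsv --out demo/cycles
counteract compare --interactions demo/interactions.tsv \
    --scenarios-file demo/scenarios.yaml --out demo/cmp
```

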