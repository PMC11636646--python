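# Methods

## Problem setting

Given `m` hypotheses with P-values `T_1..T_m` and a symmetric pairwise
distance `d_ij` between them, DART (Distance Assisted Recursive Testing)
rejects a set of hypotheses while controlling the false discovery rate
(FDR) at a nominal level `α`, under the working assumption that nearby
hypotheses tend to share their null/alternative status ("co-status").
Typical carriers of such structure are microbiome features related by
phylogeny, spatially indexed genomic or imaging features, and any panel
whose test statistics were derived independently of the distances.

The procedure has two stages.

## Stage I — the aggregation tree

The tree has `L` layers. Layer 1 holds one singleton node per hypothesis.
Layer `ℓ` is built from layer `ℓ−1` by greedily merging node pairs subject
to two constraints:

* **diameter:** `dia(A) = max_{i,j∈A} d_ij ≤ g(ℓ)` for every layer-`ℓ`
  node `A`, where `0 = g(1) ≤ g(2) ≤ … ≤ g(L)` are per-layer distance
  thresholds;
* **child count:** every node aggregates at most `M` children
  (`M ∈ {2, 3}` recommended — rejecting one node rejects all its members,
  so large nodes make the output coarse and unstable).

The greedy rule repeatedly merges the feasible pair with the smallest
merged diameter (complete linkage — the constrained quantity itself is the
merge criterion); a node formed on the current layer may absorb further
children while its child count is below `M`; nodes with no feasible
partner are carried up as single-child nodes. Ties on merged diameter are
broken by the lexicographically smallest (min member, max member) of the
union, making construction fully deterministic.

**Number of layers.** `L = max(1, floor(log_M(m / c_m)))` where `c_m`
(default 35) is the desired minimum node count on the top layer; with
fewer than ~35 top-layer nodes the error control of the testing stage
becomes unreliable, so configurations below the default draw a warning.

**Threshold selection.** For each layer in turn, every value `g` of a
candidate grid `G` with `g ≥ g(ℓ−1)` is scored by the number of nodes it
would create with at least two children (the nodes the testing stage can
actually test), and the best value wins, ties toward the smaller `g`. If
no grid value yields any merge, the tree is truncated at the current depth
with a warning.

**Default grid.** The 10%–90% deciles of the nearest-neighbour distance
distribution. A greedy step merges a node with roughly its nearest
partner, so this is the scale on which the diameter cap meaningfully
discriminates; grids built from the bulk of the full pairwise distance
distribution sit orders of magnitude above any plausible co-status
neighbourhood, and because the candidate-count score is essentially
monotone in `g`, such grids would drive the selected thresholds to the
median pairwise distance and produce trees whose nodes mix unrelated
hypotheses. The grid is the one genuinely scale-sensitive input of the
whole procedure: if domain knowledge pins the co-status scale, pass that
scale explicitly instead.

Because re-using the same threshold on a later layer still aggregates
(the child-count cap `M`, not the diameter, is usually what stops a
layer), equal consecutive thresholds are legal; the sequence `g(2..L)` is
validated as non-decreasing.

## Stage II — recursive testing with dynamic nodes

Testing proceeds bottom-up. Rejections accumulate across layers and a
rejected hypothesis is never re-tested.

**Dynamic nodes.** On layer `ℓ`, each tree node is reduced to its
*dynamic* version: its members minus all hypotheses rejected on earlier
layers. A dynamic node is a *candidate* if at least two of its children
still contribute an unrejected hypothesis (a single-child dynamic node was
already tested below). On layer 1 every unrejected singleton is a
candidate, which makes one code path serve all layers.

**Node P-values.** A candidate `S` receives the Gaussian (Stouffer)
combination of its members' original bottom-layer P-values:
`T_S = Φ̄( Σ_{j∈S} Φ̄⁻¹(T_j) / √|S| )`, with inputs clipped to
`[1e−15, 1−1e−15]` before the quantile transform to avoid infinite
z-scores. Aggregates are always recomputed from the member P-values,
never from previously aggregated node P-values. Fisher and Cauchy (ACAT)
combinations are available behind `RunConfig(aggregator=...)` for
exploration; only the Gaussian rule is covered by the calibration
guarantees, because its combination of independent uniform inputs is
exactly uniform and remains (asymptotically) super-uniform after the
survival conditioning the recursion induces.

**Layer thresholds.** Layer `ℓ` rejects every candidate with
`T_S ≤ t̂(ℓ)`, where

```
t̂(ℓ) = sup{ α_m ≤ t ≤ α :
        (Σ_{ℓ'<ℓ} n(ℓ') t̂(ℓ') + n(ℓ) t)
        / max(R(1:ℓ−1) + Σ_{S cand.} |S|·1{T_S ≤ t}, 1) ≤ α }
```

with `α_m = 1/(m log m)` the search floor, `n(ℓ)` the **total number of
hypotheses** in layer `ℓ`'s candidate set, and `R(1:ℓ−1)` the count of
previously rejected hypotheses. The numerator estimates the cumulative
count of falsely rejected *hypotheses* when null node P-values are uniform
(rejecting a null node falsely rejects all `|S|` members — hence the
size weighting; with node counts instead, the criterion is anti-conservative
even under the global null), and the denominator counts realized
discoveries, so the ratio is an FDP estimate held at or below `α`. On
layer 1 this reduces exactly to the classical step-up rule over the `m`
P-values, whose rejection set coincides with Benjamini–Hochberg whenever
the BH threshold falls inside `[α_m, α]`.

Two numerical conventions matter:

* The supremum is computed **exactly**: the denominator is a step function
  with jumps at observed node P-values, so on each step the criterion is
  linear in `t` and the largest feasible `t` has a closed form. Returning
  instead the largest feasible *observed* P-value rejects the same nodes
  but understates `t̂(ℓ)`, under-charges the layer's expected false count
  in later numerators, and measurably inflates the realized FDR (≈2× in
  the reference design).
* A layer with no feasible threshold contributes `n(ℓ)·α_m` to later
  numerators — the smallest admissible threshold, a conservative stand-in
  for the undefined quantity.

## Error metrics

For simulated data with known labels, `evaluate` reports the realized
FDP (`|ℛ∩Ω₀|/(|ℛ|∨1)`), sensitivity (`|ℛ∩Ω₁|/(|Ω₁|∨1)`) and the
**weighted node-FDP**: the summed sizes of rejected nodes containing *no*
alternative member, over total rejections. A rejected *mixed* node (some
members null, some alternative) inflates FDP but not node-FDP, so
node-FDP ≤ FDP always. The recursion's calibration guarantee attaches to
the node-level quantity; the hypothesis-level FDP exceeds it by exactly
the mixed-node premium, which is small when the distance cleanly separates
co-status groups and grows as it does not.

## Synthetic data generator

`simulate_dataset` emulates a planar multiple-testing study:

* coordinates: `x₁ ~ Normal(0, var 2)`, `x₂ ~ Uniform(0, 4)`, m = 1000
  by default; Euclidean distances;
* alternatives: 50 by default, 90% packed into 5 spatial clusters (each
  cluster = a random seed plus its nearest unassigned neighbours, all
  within `cluster_radius` = 0.3 of the seed; seeds whose neighbourhood is
  too sparse are skipped, and an unplaceable cluster raises a config
  error), 10% standalone at random locations;
* signal: alternative z-statistics `μ + Normal(0,1)` with `μ = 3`,
  two-sided normal P-values;
* nulls: exactly `Uniform(0,1)` (default); `misspecified` draws a
  t-statistic with 10 degrees of freedom but evaluates it against the
  normal reference, giving mildly anti-conservative, only asymptotically
  uniform nulls; `regression` derives every P-value from a per-feature
  simple-regression Wald test (n = 100 observations), nulls with zero
  slope, alternatives with slope `μ/√n`;
* robustness knob: `tau` exchanges that fraction of alternatives (labels
  and P-values) with randomly chosen nulls, degrading the distance /
  co-status link without changing the marginal P-value mixture.

What the generator deliberately does **not** emulate: dependence between
P-values, alternatives whose local density differs from the null
background, and survival-model (time-to-event) test statistics. Because
alternative clusters are nearest-neighbour balls inside a same-density
null continuum, every cluster boundary — and every standalone alternative
that survives layer 1 — can form a mixed node with adjacent nulls. This
is the hardest regime for the hypothesis-level FDR: in the reference
design the node-level FDP averages ≈ the nominal level (0.055 at
α = 0.05, 200 replicates, seed 0) while the hypothesis-level FDP carries
a mixed-node premium of ≈ +0.01–0.03 (0.072 at α = 0.05). Passing
calibration checks on this generator therefore demonstrates node-level
calibration and power dominance over BH, not hypothesis-level exactness
under boundary mixing; on real data the premium shrinks with the
sharpness of the distance/co-status link.

## Numerical and design choices

* All internal indexing is 0-based positional; hypothesis ids are opaque
  strings aligned between the P-value table and the distance source.
* Tree construction cost is dominated by one complete-linkage matrix and
  one edge sort per layer (`O(m²)`, ~0.3 s per tuned 1000-hypothesis
  tree with `M = 2`); `M = 3` additionally maintains a merged-diameter
  matrix and a heap of post-merge pairs.
* Benchmarks derive one sub-31-bit seed per replicate from the master
  seed via `numpy.random.SeedSequence`, and every per-replicate row
  records its seed, so any single replicate reproduces in isolation.
* The suite's replicated experiments use 200 replicates of the m = 1000
  reference design — the size at which Monte-Carlo standard errors of
  mean FDP are ≈ 0.005 — and small (m ≤ 300) instances everywhere a
  property, not a rate, is being checked.

## Known limitations

* Hypothesis-level FDR control inherits the theory's requirement that
  mixed nodes be rare; with heavy boundary mixing the realized FDP sits
  above `α` by the node premium (quantified above). Inspect
  `mean_node_fdp` vs `mean_fdp` in benchmark output to see both sides.
* Very small panels interact with the search floor: `α_m = 1/(m log m)`
  must stay below `α`, so e.g. m = 7 cannot be tested at α = 0.05 (the
  packaged toy example runs at α = 0.3 for this reason).
* P-value dependence is not modelled; strongly dependent panels void the
  calibration expectations.
* The candidate-count tuning score is monotone in `g` for most
  geometries, so the selected thresholds gravitate to the top of the
  grid; the grid's range, not the score, is the real tuning decision.
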