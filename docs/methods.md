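# Methods

## Model and procedure

`mirmod` identifies miRNA–mRNA modules in two stages. Stage one partitions
mRNAs and miRNAs into clusters that are *enriched* — tighter in
target-prediction space than chance — and stage two tests whether a miRNA
cluster's expression changes explain an mRNA cluster's expression changes
through per-pair linear models. The method assumes that (i) co-regulated
mRNAs share predicted regulators, (ii) regulation is detectable as a linear
relationship between log2 fold-changes (`u = α + βv`), and (iii) direct
regulation is repressive, so the default slope test is one-sided negative
(two-sided and positive modes exist for indirect-regulation analyses).

### Guided dissimilarity (multivariate random forest)

Trees are grown over the entities being clustered. A node splits on a map
column: entities predicted to be targeted by that miRNA go to one child, the
rest to the other. The split score is the decrease in expression-space
homogeneity `S(θ) = Σ_{l∈θ} ‖x_l − x̄_θ‖²`; among `num_cov` columns sampled
without replacement at each node, the best admissible split is taken.
Admissibility: both children must have at least `node_size` members; a node
with ≤ `node_size` members, or no admissible sampled split, is terminal.
Zero-gain splits are allowed (a constant-expression node can still split on
map structure); scores are never negative because the gain equals the
between-child sum of squares. Proximity is the fraction of trees in which
two entities co-occupy a terminal node, and `1 − proximity` is the guided
dissimilarity. Randomness comes only from per-node covariate sampling and
from tie-breaking among equal-score splits; per-tree bootstrap resampling of
rows (as in some random-forest variants) is available behind
`row_bootstrap` but off by default, since proximity, not prediction error,
is the target. When rows are bootstrapped, the tree is grown on the sample
and all entities are then routed down the tree for the co-membership count.

### PAM

k-medoids on the precomputed dissimilarity: greedy BUILD initialisation,
then a SWAP phase that evaluates every (medoid, non-medoid) exchange and
applies the one with the largest strict cost decrease until none improves —
the classic best-improvement formulation, which also vectorises cleanly
(per removed medoid, candidate costs are a single `minimum(...).sum(0)` over
the distance matrix). The seed is used only to break exact cost ties, so
results are order-invariant up to labelling whenever costs are untied.
An agglomerative comparator (scipy linkage, average or complete) is provided
for the same K-cut interface.

### Enrichment test and K selection

`ES_k` is the mean Euclidean distance of a cluster's map profiles to their
componentwise median (even counts: midpoint, so the median profile can be
fractional). The null is resampling-based: B random same-size clusters are
drawn *without replacement within a draw* from the full clustered universe
(observed members remain eligible), `W₁ = #{ES_rand ≤ ES_k}`, and the
cluster is enriched iff `W₁/B < α` strictly. Only clusters of size > 1 are
testable; `Pr_enrich` is the enriched fraction among them. The sweep
clusters at every K in a user grid and keeps the K with maximal `Pr_enrich`,
resolving ties to the smallest K; when both guided and unguided
dissimilarities are swept, the higher best-`Pr_enrich` wins and unguided
wins ties as the simpler method. On the miRNA side singleton clusters are
carried forward untested (flagged `tested = false`), because a single miRNA
can regulate a whole mRNA cluster.

### Association and module test

Per-pair OLS uses the closed-form slope with a t-test on T − 2 df, so T ≥ 3
is required. A constant miRNA profile is flagged inestimable and never
associated; a perfect fit (zero residual variance with T > 2) is treated as
p = 0 with a logged warning. A pair is associated iff it is predicted in the
map, its p-value beats the level, and its slope sign matches the requested
direction. `Assoc(m, n)` sums associated pairs between the clusters; the
bootstrap draws B random mRNA sets of size `N_n` from all mRNAs in the map
(the observed cluster is not excluded) and counts `W₂ = #{Assoc ≥ observed}`
with ≥, so an observed count of 0 can never be significant. The regulatory
verdict additionally requires every member miRNA to target strictly more
than `majority_threshold` (default 0.5) of the module's mRNAs. No
multiple-testing correction is applied across the R_mir × R_gene candidates
by default; Benjamini–Hochberg across the bootstrap p-values is available
behind `bh_adjust`.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `node_size` | 5 | minimal child size and terminal-node cut-off of the forest |
| `n_trees` (N) | 100 | proximity standard error ≤ √(0.25/N) = 0.05 per entry |
| `num_cov` | round(√X) | per-node covariate subsample, standard forest practice |
| `B` | 100 | bootstrap replicates of both tests |
| `α` | 0.05 | level of the enrichment, slope and module tests (strict `<`) |
| `direction` | negative | miRNAs repress direct targets |
| `majority_threshold` | 0.5 (exclusive) | "targets a majority" criterion |
| K grids | 4–10 (mRNA), 6–12 (miRNA) | bracket the planted structure of the default synthetic study; real studies should bracket Y/⟨cluster size⟩ |

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawning, so every artefact is bit-reproducible.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *post-processing* state of a real study: a sparse
binary map over differentially expressed entities and matched log2
fold-change profiles over T conditions (default T = 5, a short timecourse
with the reference excluded; T = 4 mirrors a patient-category design).
Planted structure:

* **miRNA families.** Each planted module's miRNAs share one latent
  standard-Gaussian trajectory plus N(0, `noise_sd`) member deviation, and
  share their off-module predicted-target column. Both mirror real
  prediction databases and co-expressed families — sequence-based predictors
  assign essentially identical target sets to family members, and with
  fully independent member columns no distance on map profiles could prefer
  grouping a family over grouping background miRNAs. At `noise_sd → 0`
  members coincide with the family mean, so every planted pair regresses to
  exactly its planted β.
* **Planted mRNAs** follow `u = α + β·(family mean profile) + N(0, noise_sd)`
  with β uniform on [−2, −1]; in-block target predictions are
  Bernoulli(0.95), background predictions Bernoulli(0.02).
* **Map membership.** Any all-zero mRNA row is assigned one predicted unit
  (a planted family or a lone background miRNA): real map matrices contain
  only entities for which at least one database predicts a pair, and a
  universe with a large mass of identical empty profiles would make random
  clusters artificially tight, which no real study exhibits.

Not emulated: probe-level noise and normalisation artefacts, upstream DE
testing, correlated background targeting (e.g. 3'-UTR length bias),
time-lagged regulation, and positive/indirect couplings. Passing recovery
tests therefore demonstrate that the statistical machinery finds genuinely
planted linear negative modules at realistic sparsity and noise — not that
the method is robust to prediction-database bias or preprocessing error.

A structure-free null generator (i.i.d. Bernoulli map, independent Gaussian
expression) calibrates both bootstrap tests. Because the enrichment and
module statistics are discrete-ish, null parameters for calibration use a
denser map (`target_prob` 0.3/0.5) so the statistics take many values and
the rank-based rejection rate is interpretable; rates land near the nominal
α = 0.05 (the enrichment test is slightly conservative through ties).

## Problem sizes and numerics

The test-suite and acceptance studies run the full pipeline on the default
synthetic study (Y = 300, X = 30, T = 5, three planted modules; 20–50 seeds)
and 200–500 null calibration tests — a few tens of seconds in total; the
method scales to the thousands-of-mRNAs regime since every bootstrap is
vectorised (argpartition subset sampling, closed-form batched OLS).
Numerical choices: exact tie comparison in both bootstrap counts (`≤`, `≥`
on identically computed floats); split-score and swap ties broken uniformly
from the seeded stream; dissimilarities symmetrised and clipped at 0;
`1e-12` tolerances when comparing costs/scores to avoid oscillating swaps on
floating-point noise.

## Known limitations

* PAM is O(K·Z²) per SWAP pass in memory-resident form — fine to a few
  thousand entities, not for genome-scale maps without subsetting.
* The slope test with T = 4–5 has few degrees of freedom; per-pair power is
  modest and the module-level bootstrap carries the inference, exactly as
  intended by the module (not pair) notion of regulation.
* `Pr_enrich`-driven K selection tends toward fragmenting background
  entities into small enriched clusters; untested singletons are excluded
  from `Pr_enrich` and false modules are filtered downstream by the
  association test, but the selected K should not be over-interpreted as the
  "true" number of groups.
* With `hclust`, medoids are undefined and the partition has no seed
  dependence; determinism relies on scipy's linkage tie rules.
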