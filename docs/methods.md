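# Methods

This note records the model as implemented, the defaults and why they are
what they are, the design choices made where more than one reading was
defensible, and what the synthetic cohorts can and cannot demonstrate.

## Regression forest

Trees are standard un-pruned CART regressors: each of the `T` trees is grown
on a bootstrap sample of the `n` training rows (drawn with replacement, size
`n`); at every node a fresh subset of `m` features is drawn without
replacement from all `M`, and the split maximizing the reduction in the
sum-of-squares node cost is taken over every candidate feature and every
achievable threshold. Thresholds are scanned at midpoints between
consecutive distinct sorted feature values within the node (at most `n−1`
candidates), which makes the search exhaustive and deterministic. A node
with fewer than `n_size` samples is not split.

Defaults `T=100`, `m=10`, `n_size=4` are the settings used throughout the
published benchmark tables for this family of models; they assume an
expression-scale feature space (hundreds of genes or more — `m=10` of 100
features gives each node a 1-in-10 look at any given gene).

Deliberate conventions, where a generic RF leaves room:

* **Tie-breaking.** Equal-gain splits resolve to the smallest feature index,
  then the smallest threshold; tied leaf majorities and tied vote modes
  resolve to the lowest category index. Every fit is bit-reproducible from
  its seed; per-tree generators are spawned from one root `SeedSequence`, so
  reproducibility does not depend on growth order.
* **Bootstrap duplicates.** Leaf means and per-type counts honour bootstrap
  multiplicity (they describe the sample the tree was fitted to); the
  nearest-neighbour weight vectors run over *distinct* original indices with
  the leaf's distinct-member count as denominator, matching the indicator
  form of the weight definition.
* **Two prediction forms.** The pooled-weight form (average the per-tree
  leaf-uniform weights, then take the weighted mean of training responses)
  is the default for plain forests because it is the form the weight algebra
  defines; the mean-of-per-tree-leaf-means form is also provided and is the
  HARF default because the method's own toy arithmetic averages leaf means
  (13.67 and 11.67 → 12.67). The two coincide exactly when bootstrap is
  disabled, which the tests exploit.

## HARF

Classification uses only the ensemble: each tree votes the majority cancer
type of the leaf the test sample reaches, and the vote mode is the inferred
type. Prediction averages the leaf means of the agreeing trees only. The
selected set cannot be empty under the mode rule (the mode received a vote);
under the two-class threshold rule it can be, in which case the model falls
back to all trees rather than fail. With one category, or all labels equal,
HARF is exactly the plain forest.

The two-class vote threshold (default 0.5) exists because the Bayes analysis
below shows 50% is only optimal for equi-probable classes with symmetric
per-tree accuracy. For more than two classes the plain mode is used; the
threshold theory is inherently binary.

## Multivariate forest and mHARF

For `r` jointly predicted drugs the node cost is the summed squared
Mahalanobis distance with the node's maximum-likelihood covariance `Λ`
(divide by `k`). `Λ` is estimated once per node being split — the parent —
and reused to score both children of every candidate split: re-estimating
inside candidate children with a handful of rows is ill-conditioned and
makes gains incomparable across candidates. A `cov_mode="child"` switch
provides the per-child variant for comparison on small fixtures. A ridge of
`1e−6 · trace(Λ)/r` keeps the inverse defined when a node is smaller than
`r`; nodes whose responses are constant up to float round-off cost 0 by
convention, as do single-row nodes.

With the parent covariance fixed, the Mahalanobis cost of any subset equals
the ordinary cost of the whitened responses `z = y L` with
`L Lᵀ = (Λ + ridge·I)⁻¹`, so the multivariate forest reuses the univariate
growth machinery with whitening as a per-node response transform. For `r=1`
whitening is a positive rescaling that cannot change which split wins, so it
is skipped, making the univariate reduction exact (identical trees at the
same seed; with scaling applied, ties that are exact in response space can
flip under float round-off).

## Vote-model theory

The idealized model treats the `T` per-tree votes as independent Bernoulli
draws with accuracies `b0` (class 0) and `b1` (class 1) and prior
`C = P(class 0)`. The 0-vote count is then binomial under either class, and
the Bayes rule thresholds it at

    T̂ = T·log β₁/log β₀ + log((1−C)/C)/log β₀,
    β₀ = b₀b₁/((1−b₀)(1−b₁)),  β₁ = b₁/(1−b₀).

Conventions: votes are integers, the rule is the strict `k > T̂`, and a count
exactly equal to an integer threshold goes to class 1 (the `≤` branch of the
posterior comparison) — this is the convention under which the equi-probable
symmetric case reduces cleanly to `k > T/2` for both parities of `T`. When
`log β₀ < 0` (anti-informative trees) the direction flips; when
`β₀ = 1` (equivalently `b0 + b1 = 1`, detected with a 1e−9 tolerance on
`log β₀`) the count carries no information, `vote_threshold` raises, and the
error collapses to the prior of whichever class the k-free rule abandons —
`1/2` for the fully uninformative symmetric case. Note the sign of the prior
term: for symmetric accuracy the threshold is
`T/2 + log((1−C)/C)/(2·log(b/(1−b)))`, i.e. a *rare* class 0 (`C < 1/2`)
demands more 0-votes than 50%, and a *dominant* class 0 is content with
fewer — this is the regime where a sub-50% vote threshold is optimal, as the
brute-force posterior crossover confirms.

The Bayes error is the pair of binomial tails on either side of the
threshold. It assumes independent trees, which real forests increasingly
violate as `T` grows; it is therefore a floor that the empirical
misclassification rate approaches and then parts from (the empirical curve
plateaus while the floor keeps falling).

`estimate_tree_accuracies` reads `b̂0, b̂1` off a fitted two-class model as
the fraction of (tree, training-sample) pairs whose leaf-majority vote
matches the true class, clipped into `[1/(2TS), 1 − 1/(2TS)]`. In-bag
estimation (the default, matching how the floor is used alongside training)
is optimistic — a sample's own label sits in its leaf — so an out-of-bag
variant is provided; under shuffled labels the OOB estimates satisfy
`b̂0 + b̂1 ≈ 1`, the uninformative regime.

## Synthetic cohorts

The generator emulates a target-inhibition view of drug response. Each cell
line carries a kinase set φ of at most 5 drawn from a pool of 10; type-1
lines draw indices from a left-truncated N(0, 1) on [0, ∞) (low indices),
type-2 lines from a right-truncated N(9, 1) on (−∞, 9] (high indices). A
drug is a normalized inhibition profile over the pool, and

    sensitivity = b × min(inhibition over kinases shared with the drug),

with `b ~ unif(0, 1)` drawn independently per cell line and an empty
intersection giving 0. Expression for 100 genes takes a per-gene beta(2, 2)
baseline scaled to [0, 10] and shared across the cohort, +N(1.25, 0.5²)
shifts on 10 marker genes in type 1, −N(1.25, 0.5²) on a down-regulated set
in type 2, and N(0, 0.4²) noise everywhere.

Free choices, fixed once and documented:

* **Index mapping.** Continuous truncated-normal draws are floored toward
  the truncation boundary (floor for the [0, ∞) law, ceiling for the
  (−∞, 9] law) and clipped to the pool. Rounding to nearest would put the
  discrete mode at index 1 (resp. 8) because the boundary index collects
  only half a unit interval; flooring preserves the continuous densities'
  boundary modes at 0 and 9. Draws repeat until 5 distinct indices or a cap
  of 25 draws, so φ keeps some sampling variability.
* **Drug profile.** Default inhibition 1.0 on the low-index half of the
  pool, decaying linearly to 0.5 at the top index. This places the type-2
  (resistant) mean sensitivity near 0.25 and the type-1 (sensitive) mean at
  the `unif(0, 1)` attenuation's ceiling of E[b] = 0.5 — with a per-line
  uniform attenuation no profile in [0, 1] can push a class mean above 0.5,
  which is the binding constraint on how far the two classes can separate.
  The profile is fully configurable.
* **Down-regulated set.** By default a *disjoint* set of 10 genes is shifted
  down in type 2 (10 up-markers, 10 down-markers, 80 null genes), the usual
  shape of simulated differential-expression data and the reading under
  which non-marker genes are class-neutral. The literal alternative — every
  non-marker gene shifted down in type 2 — is available as
  `down_set="all_remaining"`; it makes essentially every gene separate the
  classes.
* **`min` over values, not indices.** The minimum in the sensitivity rule is
  taken over inhibition values of the shared kinases (keeping sensitivities
  in [0, 1]); kinases with zero inhibition are not drug targets.
* A `class_mean_targets` option rescales each class's responses to
  prescribed means, for class-imbalance experiments where the response
  distributions rather than the pathway model are under study.

**What the cohorts show — and what they cannot.** Expression depends on the
class only; within a class it is independent of the response, whose spread
is entirely the per-line `b`. Consequently (i) classification from leaf
majorities is easy and realistic to test (misclassification < 10% at 100
trees and ~100 training lines, approaching the vote-model floor); (ii) the
per-type-vs-integrated contrast exists but is modest — the irreducible
within-class variance (up to 1/12) dominates the integrated model's
class-mixing penalty, whose scale is set by the 0.25 class-mean gap — so the
direction holds in roughly three-quarters of replicates rather than nearly
always; and (iii) per-type *tree selection* (keeping the 50% of trees with
the best per-type validation error) cannot beat the full forest here, because
trees have no within-class signal to specialize on and ranking on ~10
validation lines is noise. Real expression panels, where genes carry
within-type predictive signal, are exactly where that selection (and the
larger published contrasts) have room to appear; passing the directional
tests on these cohorts should be read with that limitation in mind.

## Evaluation harness

Cross-validation is stratified by cancer type by default (per-type errors
from an integrated model are undefined if a fold lacks a type); an
unstratified mode exists behind a flag. Pooled MSE/MAE are computed over the
union of held-out predictions, never by averaging per-fold metrics. The
two-stage competitors classify with an injectable hook (library LDA by
default): variant B predicts with trees pre-assigned to the classified type
by validation MAE (the forest is fitted on 75% of the training fold, trees
ranked on the held-out 25%), variant C applies the agreeing-trees rule after
the external classification. The tree-ranking metric is MAE on the target
type's validation samples, ties broken by tree index. The threshold sweep
refits nothing: one model per fold is reused across the grid, since the
threshold only affects the classification rule.

Problem sizes in the test suite and acceptance script (25+25-line cohorts,
30-seed replications, 20-replicate directional experiments, 100+100 lines
for the classification study) are chosen so the full suite replicates the
study design at the scale the generator defines while remaining a
single-CPU, minutes-scale run.

## Known limitations

* The Bayes floor assumes independent tree votes; it is not a bound for
  correlated ensembles and no dependence correction is attempted.
* The generator does not link expression to the kinase sets, so it cannot
  exhibit within-type predictive signal (see above).
* No missing-data handling anywhere: loading fails loudly on any missing or
  non-numeric cell.
* Feature pre-selection (e.g. relevance filtering to a few hundred genes) is
  out of scope; the forest consumes whatever feature matrix it is given.
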