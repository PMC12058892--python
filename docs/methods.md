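# Methods

## Data model and encoding

An FCPC response pattern is an asymmetric, complete binary relation on the
option set S: exactly one orientation per unordered pair.  The C(|S|, 2)
pairs are listed lexicographically by option index; for {a, b} with
index(a) < index(b) the *reference* orientation is (a, b), and a relation
is a bit vector with bit j = 1 iff pair j is reversed.  Bit vectors are
stored as integer masks, so equality, hashing and the canonical distance
|R Δ R′| = 2 · popcount(mask ⊕ mask′) are cheap.  A data set is the pair
(patterns, frequencies) with Σ F(X) = N respondents; a cluster (𝒢, p) is a
set of patterns with weights summing to one (weights can be fractional
because classification splits distance ties equally).

Two-component designs place options on a V × W grid of severity levels,
level 1 least severe, serialized as `"v:w"`.  Because options are listed
lexicographically, every pair made comparable by the pointwise order P0
has the *lower-index option preferred*, so the monotonicity axiom (MA)
pins those bits to 0 — MA membership is a single mask test.  Note that the
raw transfer axiom alone does not fix the direction of the component
orders (on the 2×2 design, 16 of the 64 relations satisfy the transfer
conditions but only 2 contain P0); `satisfies_MA` implements the
directional, operational reading — containment of P0 — which is the one
the two-component machinery uses throughout.  The monotone stimuli are
exactly the P0-comparable pairs; the conflict (non-monotone) stimuli
oppose a lower-first-component option to a lower-second-component one.

## Clustering

All methods alternate (1) minimum-discrepancy classification — each
pattern's frequency split equally among its nearest centroids, which
provably minimizes the overall discrepancy D_f for fixed centroids — and
(2) per-cluster adjustment:

* *k-modes*: per pair, keep the orientation with weighted share θ > ½;
  θ = ½ is resolved by a fair coin from the run's generator.
* *path-finding TCA*: free pairs of a linear order are its adjacent pairs
  (flipping a non-adjacent pair always breaks transitivity); under MA,
  pairs of P0 are excluded.  The free pair with minimal marginal
  p(a, b) < ½ is flipped, ties going to the lowest canonical pair index
  for reproducibility; each flip strictly decreases the average half
  distance, so termination and local optimality are guaranteed.
* *greedy TCA*: all 2·C(n,2) ordered pairs are processed in decreasing
  marginal order (ties by ordered-pair index; a seeded-random tie mode
  exists for robustness studies) and inserted when the relation stays
  acyclic, checked by an incremental DFS reachability test.  Under MA the
  P0 marginals are forced to 1, which is equivalent to seeding with P0.

Convergence: duplicate adjusted centroids merge (a structure is a set),
and a merge can transiently *raise* the overall discrepancy before later
passes recover, so the loop does not stop at the first non-improving pass.
It runs until the centroid set reaches a fixed point or revisits a
previous set, with a patience of 3 consecutive passes without an
improvement beyond `tol` (default 0 — the weighted discrepancy is integer
on integer frequencies), capped at `max_iter = 100`; the best solution
visited is returned and the reported trace is the running best, hence
non-increasing.  Empty clusters carry their centroid unchanged and are
dropped at termination if still empty.  Initial centroids for the TCA
methods are random linear orders (random linear extensions of P0 under
MA), since the path-finding procedure needs an admissible start; k-modes
may start from arbitrary relations.

TCA is a steepest-descent local search and can stall in poor local minima
when started far from a cluster's mass; greedy TCA rebuilds from the
marginals globally and is empirically the stronger variant on
one-component designs, while the two are close (TCA slightly ahead under
heavy noise with many states) on MA-constrained designs.  Under moderate
noise with few states per cluster, plain k-modes' majority vote is a very
good denoiser; the transitivity constraint pays off as noise or the number
of states grows.

## Synthetic data

The generator draws a structure of `c` distinct states — uniform random
permutations for one-component designs; random linear extensions of P0
(uniform among currently addable pairs, which matches the sequential
procedure but is *not* the uniform distribution over linear extensions)
for two-component designs — assigns each of N respondents a state
uniformly with replacement, and inverts each pair (a, b) of the state
independently with probability β_ab.  The β are drawn once per *ordered*
pair, uniformly in an interval (lo, hi] ⊆ [0, .5] (the no-error condition
sets β ≡ 0), and held fixed for a condition.  Default study sizes follow
the designs the methods target: 10 options (45 stimuli) with
c ∈ {10, 50, 100} and N ∈ {50, 500} for one-component conditions; the
4×4 grid (16 options, 120 stimuli) with N = 400 for the selection study.

What the generator does not emulate: non-uniform state mixtures,
correlated errors across pairs, respondent-level error heterogeneity,
missing responses, or order effects.  Passing tests therefore show that
the algorithms recover the generating structure under independent
pair-level noise, not that real populations satisfy those assumptions.

## Evaluation and selection

TPR is reported in both of its readings, which differ when the extracted
structure over-extracts: `tpr` = |𝒫̂ ∩ 𝒫| / |𝒫̂| (share of extracted states
that are true) and `true_state_recovery` = |𝒫̂ ∩ 𝒫| / |𝒫| (share of true
states recovered).  State identity is exact bitwise equality.  The
discrepancy δ(𝒜, ℬ) averages, over 𝒜, the minimum symmetric-difference
distance to ℬ; it is asymmetric, zero iff 𝒜 ⊆ ℬ, and counted in ordered
pairs (twice the number of disagreeing stimuli; a `half=True` variant
counts stimuli).

Cardinality selection grows candidates incrementally: the k = 1 solution
adjusts a single centroid on the whole training set; each later candidate
seeds the previous solution plus the training pattern farthest (in
minimum distance) from it, projected into the admissible class by greedy
TCA on a singleton cluster.  Seeds that merge back during re-clustering
are remembered and skipped; after 3 consecutive merge-backs the extension
is considered exhausted.  The selected candidate minimizes
M = max{δ(𝒱, 𝒫̂), δ(𝒫̂, 𝒱)} with ties going to the smaller cardinality;
`criterion="validation"` scores on a held-out third of respondents
(repeated over partitions), while `criterion="train"` skips the split and
scores on the full sample — the mode for simulation studies where the
ground truth is known and no held-out test of the structure is needed.
Because δ(train, 𝒫̂) keeps decreasing as states are added, the train-mode
criterion tends to select the largest candidate; over-extraction (more
states than the truth, the extras within a few flips of true states) is
the expected behavior of the procedure under noise, and the recovery
reading of TPR is the informative one in that regime.

## The latent class model

With states K as latent classes, P(X) = Σ_K P(X|K) π_K and P(X|K) is a
product over stimuli: a pair held by the state contributes β (observed
reversed) or 1 − β.  The preference-specific coupling η_(a,b) = β_(b,a)
is structural — one error parameter per ordered pair, two per stimulus —
giving (|𝒫| − 1) + 2·C(n,2) free parameters.  EM runs on pattern
frequencies with closed-form M-steps; error rates are clipped to
[1e−6, .5 − 1e−6] (a rate above ½ would re-encode the state), π starts
uniform and errors at 0.1, and the run stops when the log-likelihood
gains less than `tol = 1e−7`, returning the best iterate.  An orientation
held by *no* state does not enter the likelihood and keeps its
initialization; recovery experiments therefore check the identifiable
parameters (or use structures covering both orientations).

AICc uses the respondent count N: AICc = AIC + 2k(k+1)/(N−k−1).  The
Pearson X² uses one cell per distinct observed pattern plus a pooled
"all other patterns" cell; because the full pattern space is astronomically
sparse the statistic has no usable asymptotic reference, and its p value
comes from a parametric bootstrap (default 1000 replicates) in which each
replicate is simulated from the fitted model, refitted, and scored under
the same cell *rule* applied to its own patterns — scoring replicates on
the original cell list would break exchangeability, since the observed
pooled cell is empty by construction.

## Scaled-down study sizes

The statistical test suite runs reduced versions of the reference
simulation designs, chosen to keep the whole suite around a minute while
leaving the Monte-Carlo error small against the asserted tolerances: the
selection study runs 20 replicates per error condition (c = 10 true
states, 4×4 MA design, N = 400, k up to 40); the method-ordering
comparisons use 3 replicates per cardinality at the (.20, .30]
one-component interval and 6 replicates at the (.40, .50] MA interval,
where the orderings are robust; EM recovery uses N = 5000 on five
options and bootstrap calibration 12 × 200 replicates on four options.

## Known limitations

Neither TCA variant guarantees a global optimum (their global-minimum hit
rate against exhaustive enumeration on 4 options is recorded by the test
suite, not asserted).  The incremental-extension seeding rule and its
stopping patience are this package's own design; other rules fit behind
the same interface.  Partial or missing responses are excluded upstream
(complete-case analysis), weak orders with ties are out of scope, and no
formal identifiability analysis of the latent class model is performed —
on realistic designs the full Jacobian over the pattern space is
intractable, and weakly separated states visibly trade state weight
against pair error rates in the recovery experiments.
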