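# korders

Extracting transitive preference states from forced-choice paired-comparison
(FCPC) data by *k*-orders clustering — *k*-modes with transitive centroid
adjustment — plus the simulation engine, evaluation indexes, model-selection
procedure, and the latent-class model (BLIM) used to validate extracted
structures.

## The problem

In an FCPC experiment every respondent chooses one option from each
unordered pair of a stimulus set, so a complete record is an asymmetric,
complete binary relation on the options.  Populations are heterogeneous: a
handful of distinct *preference states* (ideally strict linear orders —
transitive full rankings) coexist, and aggregate statistics can be
intransitive even when every individual is transitive (the Condorcet
paradox).  Classical *k*-modes clustering with the Hamming/symmetric-difference
distance recovers groups but its element-wise modal centroids may be
intransitive and overfit noise.

*k*-orders keeps the *k*-modes classification step — each pattern X with
frequency F(X) is split equally among the centroids at minimum canonical
distance |X Δ C| — and replaces the adjustment step with a **transitive
centroid adjustment** (TCA).  For a cluster (𝒢, p) with marginal pair
proportions p(a,b) = Σ_{R ∋ (a,b)} p(R), the average half distance of a
relation R from the cluster is

    d(R, 𝒢) = ½ Σ_{R′∈𝒢} p(R′) |R Δ R′| = Σ_{(a,b) ∉ R} p(a, b),

and flipping a pair (a,b) of a linear order L changes d by
p(a,b) − p(b,a), so:

* **path-finding TCA** repeatedly flips the *free* pair (one whose flip
  keeps L inside the admissible class ℒ*) with the smallest non-modal
  marginal p(a,b) < ½, strictly decreasing d until a local minimum;
* **greedy TCA** inserts all ordered pairs in decreasing order of p(a,b),
  keeping the relation acyclic; the result is always a strict linear order
  and a local minimum.

Two-component options (v, w) ∈ V × W with linearly ordered levels add the
**monotonicity axiom** (MA): orderings of one component transfer across
levels of the other, operationalized as containment of the pointwise order
P0.  Setting p ≡ 1 on the pairs of P0 makes both procedures respect MA
(for greedy TCA this equals starting from P0 instead of ∅).

The extracted structure 𝒫̂ is compared to a truth 𝒫 by the true-positive
rate and the asymmetric average minimum discrepancy
δ(𝒜, ℬ) = (1/|𝒜|) Σ_A min_B |A Δ B|; its cardinality is chosen by an
incremental extension plus the cross-validated criterion
M = max{δ(𝒱, 𝒫̂), δ(𝒫̂, 𝒱)}; and the structure is testable on data via the
basic local independence model, a restricted latent class model whose
classes are the states, with one error rate per ordered pair under the
coupling η_(a,b) = β_(b,a), fitted by EM and assessed by AIC/AICc and a
parametric bootstrap of the Pearson X².

## Worked example

`examples/simulate_and_cluster.py` simulates 500 respondents from 50
random rankings of 10 options with per-pair inversion probabilities in
(.20, .30], then runs the three methods on the same data:

```
500 distinct patterns from 500 respondents

kmodes  delta(extracted, true) = 18.68   recovery = 0.02   all centroids transitive: False
tca     delta(extracted, true) = 17.36   recovery = 0.00   all centroids transitive: True
greedy  delta(extracted, true) = 11.76   recovery = 0.08   all centroids transitive: True
```

delta is the average distance (in ordered pairs) from an extracted state to
the nearest true state — under this much noise the transitivity constraint
pays: both *k*-orders variants land closer to the truth than *k*-modes,
whose centroids are not even guaranteed to be orders.  The other example
scripts cover the MA-constrained two-component design
(`two_component_ma.py`), cardinality selection (`model_selection.py`),
latent-class validation with the health/economy aggregates
(`blim_validation.py`), and the neighbor-graph export
(`structure_graph.py`).  A thin CLI wraps the same calls:
`korders simulate|cluster|select|evaluate|blim|graph --help`.

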