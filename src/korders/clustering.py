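"""k-modes and k-orders clustering of paired-comparison response patterns.

All three algorithms share the classification step: each observed response
pattern is assigned to the centroid(s) at minimum canonical
symmetric-difference distance, with ties split equally (the
minimum-discrepancy partition function).  They differ only in how a
cluster's centroid is adjusted:

* ``kmodes`` — element-wise majority per pair (the mode), which can yield
  an intransitive centroid on cyclic-majority data (the Condorcet paradox);
* ``tca`` — path-finding transitive centroid adjustment: starting from the
  current centroid, repeatedly flip the free pair with the smallest
  non-modal marginal proportion, so every step strictly decreases the
  average half distance and the result is a strict linear order that is a
  local minimum;
* ``greedy`` — greedy transitive centroid adjustment: insert the ordered
  pairs in decreasing order of marginal proportion, keeping the relation
  acyclic; the result is again a strict linear order and a local minimum.

Two-component (monotonicity-axiom) constraints enter through the marginal
proportions: every pair fixed by the pointwise order P0 is given marginal 1,
so TCA can never flip it and greedy TCA inserts it first — equivalent to
seeding greedy TCA with P0 itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .relations import (
    ConstraintSet,
    PairUniverse,
    PreferenceStructure,
    Relation,
)

__all__ = [
    "Dataset",
    "PartitionFunction",
    "Cluster",
    "ClusteringResult",
    "classify",
    "overall_discrepancy",
    "kmodes_adjust",
    "marginal_proportions",
    "avg_half_distance",
    "avg_half_distance_definition",
    "tca_adjust",
    "greedy_tca_adjust",
    "run_korders",
    "run_kmodes",
]


@dataclass(frozen=True)
class Dataset:
    """Observed response patterns with nonnegative frequencies."""

    universe: PairUniverse
    patterns: tuple[Relation, ...]
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.patterns) != len(self.freqs):
            raise ValueError("patterns and freqs length mismatch")
        if len(set(self.patterns)) != len(self.patterns):
            raise ValueError("patterns must be distinct (aggregate duplicates)")
        f = np.asarray(self.freqs, dtype=float)
        if np.any(f < 0) or f.sum() <= 0:
            raise ValueError("frequencies must be nonnegative with positive total")
        for r in self.patterns:
            if r.universe != self.universe:
                raise ValueError("pattern universe mismatch")
        object.__setattr__(self, "freqs", tuple(float(x) for x in f))

    @classmethod
    def from_patterns(
        cls, universe: PairUniverse, patterns: Sequence[Relation]
    ) -> "Dataset":
        """Aggregate a respondent-level list of relations into frequencies."""
        counts: dict[Relation, float] = {}
        for r in patterns:
            counts[r] = counts.get(r, 0.0) + 1.0
        pats = tuple(sorted(counts, key=lambda r: r.mask))
        return cls(universe, pats, tuple(counts[r] for r in pats))

    @property
    def n(self) -> float:
        return float(sum(self.freqs))

    def bit_matrix(self) -> np.ndarray:
        """Patterns × pairs matrix of bits (1 = reversed orientation)."""
        return np.stack([p.bit_array() for p in self.patterns])


def _bit_matrix(relations: Sequence[Relation]) -> np.ndarray:
    return np.stack([r.bit_array() for r in relations])


def _distance_matrix(patterns: Sequence[Relation], centroids: Sequence[Relation]) -> np.ndarray:
    """Canonical distances |X Δ C|, patterns × centroids."""
    x = _bit_matrix(patterns).astype(np.uint8)
    c = _bit_matrix(centroids).astype(np.uint8)
    return 2 * (x[:, None, :] != c[None, :, :]).sum(axis=2)


@dataclass(frozen=True)
class PartitionFunction:
    """Weights f(X, C) distributing each pattern's frequency over centroids.

    Satisfies (C1) f(X, C) ≥ 0 and (C2) Σ_C f(X, C) = F(X).
    """

    data: Dataset
    centroids: tuple[Relation, ...]
    values: np.ndarray  # patterns × centroids
    distances: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.data.patterns), len(self.centroids)):
            raise ValueError("partition values have wrong shape")
        if np.any(v < -1e-12):
            raise ValueError("(C1) violated: negative weight")
        if not np.allclose(v.sum(axis=1), np.asarray(self.data.freqs), atol=1e-9):
            raise ValueError("(C2) violated: row sums differ from frequencies")
        object.__setattr__(self, "values", v)
        if self.distances is None:
            object.__setattr__(
                self, "distances", _distance_matrix(self.data.patterns, self.centroids)
            )

    def cluster(self, k: int) -> "Cluster":
        """The cluster (𝒢, p) of centroid ``k``: positive-weight patterns, normalized."""
        col = self.values[:, k]
        total = col.sum()
        if total <= 0:
            raise ValueError(f"cluster {k} is empty")
        keep = col > 0
        pats = tuple(p for p, m in zip(self.data.patterns, keep) if m)
        return Cluster(self.data.universe, pats, tuple(col[keep] / total))

    def cluster_mass(self, k: int) -> float:
        return float(self.values[:, k].sum())


@dataclass(frozen=True)
class Cluster:
    """A cluster (𝒢, p): response patterns with weights summing to 1.

    Weights may be fractional because classification splits tied patterns
    equally among their nearest centroids.
    """

    universe: PairUniverse
    patterns: tuple[Relation, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.patterns) != len(w):
            raise ValueError("patterns and weights length mismatch")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    def reference_marginals(self, p0_mask: int = 0) -> np.ndarray:
        """p(reference orientation) per canonical pair.

        With a nonzero ``p0_mask`` (pairs fixed by the pointwise order P0),
        those marginals are forced to 1: P0 pairs are always modal, which is
        how the monotonicity axiom is enforced inside both TCA procedures.
        """
        bits = _bit_matrix(self.patterns)
        w = np.asarray(self.weights)
        p_ref = 1.0 - w @ bits  # bit 1 = reversed, so reference share is 1 - mean bit
        if p0_mask:
            for j in range(self.universe.n_pairs):
                if (p0_mask >> j) & 1:
                    p_ref[j] = 1.0
        return p_ref

    def marginal(self, p_ref: np.ndarray, i: int, k: int) -> float:
        """Marginal proportion p(i, k) of the ordered option-index pair (i, k)."""
        j = self.universe.pair_index(i, k)
        return float(p_ref[j]) if i < k else float(1.0 - p_ref[j])


def classify(data: Dataset, centroids: PreferenceStructure | Sequence[Relation]) -> PartitionFunction:
    """Minimum-discrepancy partition: split each pattern's frequency equally
    among the centroids at minimum canonical distance."""
    cents = tuple(centroids)
    if not cents:
        raise ValueError("centroid set is empty")
    dist = _distance_matrix(data.patterns, cents)
    dmin = dist.min(axis=1, keepdims=True)
    nearest = dist == dmin
    freqs = np.asarray(data.freqs)
    values = nearest * (freqs / nearest.sum(axis=1))[:, None]
    return PartitionFunction(data, cents, values, dist)


def overall_discrepancy(partition: PartitionFunction) -> float:
    """Eq. D_f(ℛ, 𝒞) = Σ_C Σ_X f(X, C)·|X Δ C|, the sum of within-class dissimilarities."""
    return float((partition.values * partition.distances).sum())


def marginal_proportions(cluster: Cluster) -> dict[tuple[str, str], float]:
    """Marginal proportion p(a, b) for every ordered option pair."""
    p_ref = cluster.reference_marginals()
    opts = cluster.universe.options
    out: dict[tuple[str, str], float] = {}
    for j, (i, k) in enumerate(cluster.universe.pairs):
        out[(opts[i], opts[k])] = float(p_ref[j])
        out[(opts[k], opts[i])] = float(1.0 - p_ref[j])
    return out


def avg_half_distance(rel: Relation, cluster: Cluster, p0_mask: int = 0) -> float:
    """Average half distance d(R, 𝒢) via the pair-marginal identity.

    d(R, 𝒢) = Σ_{(a,b) ∉ R} p(a, b): the sum, over ordered pairs missing
    from R, of their marginal proportions in the cluster.  Equal to the
    definition ``(1/2)·Σ_R' p(R')·|R Δ R'|`` (see
    :func:`avg_half_distance_definition`; a property test asserts the two
    agree).
    """
    p_ref = cluster.reference_marginals(p0_mask)
    bits = rel.bit_array()
    # bit 1: relation holds the reversed orientation, so the *missing* pair
    # is the reference one with marginal p_ref; bit 0: missing pair is the
    # reversed one with marginal 1 - p_ref.
    return float(np.where(bits == 1, p_ref, 1.0 - p_ref).sum())


def avg_half_distance_definition(rel: Relation, cluster: Cluster) -> float:
    """d(R, 𝒢) straight from the definition (weighted half distances)."""
    return 0.5 * sum(
        w * rel.distance(r) for r, w in zip(cluster.patterns, cluster.weights)
    )


def kmodes_adjust(cluster: Cluster, rng: np.random.Generator) -> Relation:
    """Element-wise centroid adjustment rule (the mode).

    Per pair, keep the orientation whose weighted share θ exceeds 1/2;
    resolve θ = 1/2 by a fair coin from ``rng``.  The output need not be
    transitive.
    """
    p_ref = cluster.reference_marginals()
    mask = 0
    for j, theta in enumerate(p_ref):
        if theta < 0.5:
            mask |= 1 << j
        elif theta == 0.5 and rng.random() < 0.5:
            mask |= 1 << j
    return Relation(cluster.universe, mask)


def _p0_mask_for(constraints: Optional[ConstraintSet]) -> int:
    if constraints is not None and constraints.kind == "linear_orders_with_MA":
        assert constraints.design is not None
        return constraints.design.p0_pair_mask()
    return 0


def tca_adjust(
    start: Relation,
    cluster: Cluster,
    constraints: Optional[ConstraintSet] = None,
) -> Relation:
    """Path-finding transitive centroid adjustment.

    From ``start`` (a member of the admissible class), repeatedly flip the
    free pair (a, b) with p(a, b) < 1/2 and p(a, b) minimal among free
    pairs; ties go to the lowest canonical pair index.  Each flip strictly
    decreases the average half distance, so the procedure terminates at a
    local minimum of the admissible class.
    """
    constraints = constraints or ConstraintSet()
    if start not in constraints:
        raise ValueError("start relation is not in the constraint set")
    universe = cluster.universe
    p0_mask = _p0_mask_for(constraints)
    p_ref = cluster.reference_marginals(p0_mask)

    ranking = list(start.ranking())
    mask = start.mask
    max_steps = 4 * universe.n_pairs * universe.n_pairs + 4
    for _ in range(max_steps):
        best = None  # (p, pair_index, position)
        for pos in range(len(ranking) - 1):
            i, k = ranking[pos], ranking[pos + 1]
            j = universe.pair_index(i, k)
            if (p0_mask >> j) & 1:
                continue  # pair fixed by the pointwise order: never free
            p = p_ref[j] if i < k else 1.0 - p_ref[j]
            if p < 0.5 and (best is None or (p, j) < (best[0], best[1])):
                best = (p, j, pos)
        if best is None:
            break
        _, j, pos = best
        ranking[pos], ranking[pos + 1] = ranking[pos + 1], ranking[pos]
        mask ^= 1 << j
    else:  # pragma: no cover - the strict-decrease argument forbids this
        raise RuntimeError("TCA failed to terminate")
    return Relation(universe, mask)


def greedy_tca_adjust(
    cluster: Cluster,
    start: Sequence[tuple[int, int]] = (),
    constraints: Optional[ConstraintSet] = None,
    rng: Optional[np.random.Generator] = None,
) -> Relation:
    """Greedy transitive centroid adjustment.

    Processes every ordered pair in decreasing order of its marginal
    proportion (ties by ordered-pair index, or seeded-random when ``rng``
    is given) and inserts it whenever the relation stays acyclic.  The
    result is a strict linear order containing ``start``.  ``start`` must
    itself be acyclic — the empty relation, or the pointwise order P0 when
    the monotonicity axiom is required (equivalently, MA constraints force
    the P0 marginals to 1 so those pairs are inserted first).
    """
    universe = cluster.universe
    n = universe.n_options
    p0_mask = _p0_mask_for(constraints)
    p_ref = cluster.reference_marginals(p0_mask)

    adj: list[set[int]] = [set() for _ in range(n)]

    def reaches(src: int, dst: int) -> bool:
        stack, seen = [src], {src}
        while stack:
            node = stack.pop()
            if node == dst:
                return True
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    def try_add(i: int, k: int) -> bool:
        if k in adj[i]:
            return True
        if reaches(k, i):
            return False
        adj[i].add(k)
        return True

    for i, k in start:
        if not try_add(i, k):
            raise ValueError("start relation is cyclic")

    # all ordered pairs, ranked by decreasing marginal proportion
    pairs = []
    for j, (i, k) in enumerate(universe.pairs):
        pairs.append((i, k, float(p_ref[j]), 2 * j))
        pairs.append((k, i, float(1.0 - p_ref[j]), 2 * j + 1))
    if rng is None:
        pairs.sort(key=lambda t: (-t[2], t[3]))
    else:
        jitter = rng.random(len(pairs))
        pairs.sort(key=lambda t: (-t[2], jitter[t[3]]))

    for i, k, _, _ in pairs:
        try_add(i, k)

    mask = 0
    for j, (i, k) in enumerate(universe.pairs):
        if i in adj[k]:
            mask |= 1 << j
        elif k not in adj[i]:  # pragma: no cover - completeness is guaranteed
            raise RuntimeError("greedy TCA produced an incomplete relation")
    return Relation(universe, mask)


@dataclass(frozen=True)
class ClusteringResult:
    """Outcome of a clustering run."""

    centroids: PreferenceStructure
    partition: PartitionFunction
    discrepancy_trace: tuple[float, ...]
    iterations: int
    converged: bool
    empty_clusters_dropped: int = 0

    @property
    def discrepancy(self) -> float:
        return self.discrepancy_trace[-1]


def run_korders(
    data: Dataset,
    init: PreferenceStructure,
    method: str = "tca",
    constraints: Optional[ConstraintSet] = None,
    tol: float = 0.0,
    max_iter: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> ClusteringResult:
    """Alternate classification and centroid adjustment until convergence.

    Parameters
    ----------
    method
        ``"kmodes"`` (unconstrained modes), ``"tca"`` (path-finding
        transitive centroid adjustment) or ``"greedy"`` (greedy TCA).
    constraints
        Admissible centroid class for the TCA methods; defaults to plain
        strict linear orders.  For ``kmodes`` the initial centroids may be
        arbitrary relations.
    tol
        Stop when the overall discrepancy improves by ``tol`` or less
        between iterations (the discrepancy is integer-weighted, so the
        default 0 stops at the first non-improving pass).

    Notes
    -----
    Empty clusters keep their centroid unchanged during the run and are
    dropped at termination if still empty.  Duplicate adjusted centroids
    merge (the centroid collection is a set), which can transiently raise
    the overall discrepancy before later passes recover; the loop therefore
    runs until the centroid set reaches a fixed point (or revisits a
    previous set, or the discrepancy stops improving by more than ``tol``
    for a few consecutive passes), and the *best* solution encountered is
    returned.  The recorded trace is the running best, hence
    non-increasing.
    """
    if method not in ("kmodes", "tca", "greedy"):
        raise ValueError(f"unknown method {method!r}")
    if rng is None:
        rng = np.random.default_rng()
    constraints = constraints or ConstraintSet()
    if method in ("tca", "greedy"):
        for c in init:
            if c not in constraints:
                raise ValueError("initial centroid outside the constraint set")

    p0_pairs: tuple[tuple[int, int], ...] = ()
    if method == "greedy" and constraints.kind == "linear_orders_with_MA":
        assert constraints.design is not None
        p0_pairs = tuple(sorted(constraints.design.p0_pairs()))

    patience = 3  # non-improving passes tolerated (merges can bump D up)
    centroids: list[Relation] = list(init)
    partition = classify(data, centroids)
    d = overall_discrepancy(partition)
    best = (d, centroids, partition)
    trace = [d]
    visited = {frozenset(c.mask for c in centroids)}
    converged = False
    iterations = 0
    stale = 0
    for _ in range(max_iter):
        iterations += 1
        new_centroids: list[Relation] = []
        seen: set[Relation] = set()
        for k, c in enumerate(centroids):
            if partition.cluster_mass(k) <= 0:
                adjusted = c  # empty cluster: carry the centroid over
            else:
                cl = partition.cluster(k)
                if method == "kmodes":
                    adjusted = kmodes_adjust(cl, rng)
                elif method == "tca":
                    adjusted = tca_adjust(c, cl, constraints)
                else:
                    adjusted = greedy_tca_adjust(cl, p0_pairs, constraints)
            if adjusted not in seen:
                seen.add(adjusted)
                new_centroids.append(adjusted)
        key = frozenset(c.mask for c in new_centroids)
        fixed_point = key == frozenset(c.mask for c in centroids)
        partition = classify(data, new_centroids)
        d = overall_discrepancy(partition)
        centroids = new_centroids
        if d < best[0] - tol:
            best = (d, centroids, partition)
            stale = 0
        else:
            if d < best[0]:
                best = (d, centroids, partition)
            stale += 1
        trace.append(best[0])
        if fixed_point or key in visited or stale >= patience:
            converged = True
            break
        visited.add(key)

    _, centroids, partition = best
    # drop clusters that remained empty
    masses = partition.values.sum(axis=0)
    keep = [k for k, m in enumerate(masses) if m > 0]
    dropped = len(centroids) - len(keep)
    if dropped:
        centroids = [centroids[k] for k in keep]
        partition = classify(data, centroids)
    return ClusteringResult(
        centroids=PreferenceStructure(tuple(centroids)),
        partition=partition,
        discrepancy_trace=tuple(trace),
        iterations=iterations,
        converged=converged,
        empty_clusters_dropped=dropped,
    )


def run_kmodes(
    data: Dataset,
    init: PreferenceStructure,
    tol: float = 0.0,
    max_iter: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> ClusteringResult:
    """The unconstrained baseline: :func:`run_korders` with ``method="kmodes"``."""
    return run_korders(data, init, method="kmodes", tol=tol, max_iter=max_iter, rng=rng)
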