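"""Preference relations as bit vectors over a canonical pair universe.

A forced-choice paired-comparison (FCPC) experiment presents one stimulus
per unordered pair of options; each respondent must pick one option per
stimulus.  The complete record of a respondent is therefore an asymmetric,
complete binary relation on the option set: exactly one orientation per
unordered pair.  This module provides that representation together with the
order-theoretic predicates (transitivity, acyclicity, the monotonicity
axiom for two-component options) and the elementary moves (pair flips, free
pairs, neighborhoods) on which the clustering algorithms are built.

Encoding
--------
The ``C(n, 2)`` unordered pairs of an option set are listed in a fixed
lexicographic order (by option index).  For a pair ``{a, b}`` with
``index(a) < index(b)`` the *reference* orientation is ``(a, b)``.  A
relation is a bit vector of that length where bit ``j = 1`` if and only if
the relation contains the reversed orientation of pair ``j``.  The vector
is stored as a Python integer mask, which makes relations cheap to hash,
compare, and XOR (the symmetric-difference distance is twice the popcount
of the XOR of two masks).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "PairUniverse",
    "Relation",
    "PreferenceStructure",
    "TwoComponentDesign",
    "ConstraintSet",
    "is_acyclic",
    "perm_to_order",
    "all_relations",
    "all_linear_orders",
]


@dataclass(frozen=True)
class PairUniverse:
    """The option set together with its canonical pair ordering.

    Parameters
    ----------
    options
        Ordered sequence of distinct option identifiers (opaque strings).
    """

    options: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.options)) != len(self.options):
            raise ValueError("options must be distinct")
        if len(self.options) < 2:
            raise ValueError("a pair universe needs at least two options")
        object.__setattr__(self, "options", tuple(self.options))

    @classmethod
    def from_options(cls, options: Iterable[str]) -> "PairUniverse":
        return cls(tuple(str(o) for o in options))

    @property
    def n_options(self) -> int:
        return len(self.options)

    @property
    def n_pairs(self) -> int:
        n = len(self.options)
        return n * (n - 1) // 2

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        """All unordered pairs as (i, k) index tuples, i < k, lexicographic."""
        n = len(self.options)
        return tuple((i, k) for i in range(n) for k in range(i + 1, n))

    def pair_index(self, i: int, k: int) -> int:
        """Canonical index of the unordered pair of option indices {i, k}."""
        if i == k:
            raise ValueError("pair options must be distinct")
        if i > k:
            i, k = k, i
        n = len(self.options)
        # offset of row i in the lexicographic listing
        return i * n - i * (i + 1) // 2 + (k - i - 1)

    def option_index(self, option: str) -> int:
        try:
            return self.options.index(option)
        except ValueError as exc:
            raise KeyError(f"unknown option {option!r}") from exc

    def pair_label(self, j: int) -> str:
        i, k = self.pairs[j]
        return f"{self.options[i]}|{self.options[k]}"

    def ordered_pair_index(self, i: int, k: int) -> int:
        """Index of the *ordered* pair (i, k) in the 2·C(n,2) listing.

        Ordered pairs are numbered ``2·j + o`` where ``j`` is the unordered
        pair index and ``o`` is 0 for the reference orientation and 1 for
        the reversed one.
        """
        j = self.pair_index(i, k)
        return 2 * j + (1 if i > k else 0)


@dataclass(frozen=True)
class Relation:
    """An asymmetric, complete binary relation on a pair universe.

    ``mask`` holds one bit per canonical unordered pair; bit ``j = 1``
    means the relation contains the reversed orientation of pair ``j``.
    By construction every instance is asymmetric and complete.
    """

    universe: PairUniverse
    mask: int

    def __post_init__(self) -> None:
        if not 0 <= self.mask < (1 << self.universe.n_pairs):
            raise ValueError("mask out of range for this universe")

    # -- constructors -------------------------------------------------

    @classmethod
    def from_bits(cls, universe: PairUniverse, bits: Sequence[int]) -> "Relation":
        if len(bits) != universe.n_pairs:
            raise ValueError("bit vector has wrong length")
        mask = 0
        for j, b in enumerate(bits):
            if b not in (0, 1):
                raise ValueError("bits must be 0 or 1")
            mask |= b << j
        return cls(universe, mask)

    @classmethod
    def from_pairs(
        cls, universe: PairUniverse, pairs: Iterable[tuple[str, str]]
    ) -> "Relation":
        """Build from a set of ordered option pairs (one per stimulus)."""
        seen: dict[int, int] = {}
        for a, b in pairs:
            ia, ib = universe.option_index(a), universe.option_index(b)
            if ia == ib:
                raise ValueError(f"pair ({a!r}, {b!r}) is not a pair of distinct options")
            j = universe.pair_index(ia, ib)
            bit = 1 if ia > ib else 0
            if j in seen and seen[j] != bit:
                raise ValueError(f"both orientations given for pair {universe.pair_label(j)}")
            seen[j] = bit
        if len(seen) != universe.n_pairs:
            raise ValueError("an orientation is missing for at least one pair")
        mask = 0
        for j, bit in seen.items():
            mask |= bit << j
        return cls(universe, mask)

    # -- views ---------------------------------------------------------

    def bits(self) -> tuple[int, ...]:
        return tuple((self.mask >> j) & 1 for j in range(self.universe.n_pairs))

    def bit_array(self) -> np.ndarray:
        # cached: clustering stacks these arrays in every classification pass
        cached = self.__dict__.get("_bit_array")
        if cached is None:
            cached = np.fromiter(
                self.bits(), dtype=np.uint8, count=self.universe.n_pairs
            )
            cached.setflags(write=False)
            object.__setattr__(self, "_bit_array", cached)
        return cached

    def to_pairs(self) -> frozenset[tuple[str, str]]:
        """The set-of-ordered-pairs view (inverse of :meth:`from_pairs`)."""
        opts = self.universe.options
        out = []
        for j, (i, k) in enumerate(self.universe.pairs):
            if (self.mask >> j) & 1:
                out.append((opts[k], opts[i]))
            else:
                out.append((opts[i], opts[k]))
        return frozenset(out)

    def to_index_pairs(self) -> frozenset[tuple[int, int]]:
        out = []
        for j, (i, k) in enumerate(self.universe.pairs):
            if (self.mask >> j) & 1:
                out.append((k, i))
            else:
                out.append((i, k))
        return frozenset(out)

    def contains(self, a: str, b: str) -> bool:
        """True iff the relation holds ``a`` preferred to ``b``."""
        ia, ib = self.universe.option_index(a), self.universe.option_index(b)
        j = self.universe.pair_index(ia, ib)
        bit = (self.mask >> j) & 1
        return bit == (1 if ia > ib else 0)

    # -- algebra --------------------------------------------------------

    def distance(self, other: "Relation") -> int:
        """Canonical symmetric-difference distance |R Δ R'|.

        Equals twice the Hamming distance of the bit vectors, since each
        disagreeing pair contributes both orientations to the symmetric
        difference.
        """
        if self.universe != other.universe:
            raise ValueError("relations live on different universes")
        return 2 * (self.mask ^ other.mask).bit_count()

    def flip(self, a: str, b: str) -> "Relation":
        """Replace (a, b) with its inverse: the operation R − (a, b)."""
        if not self.contains(a, b):
            raise ValueError(f"({a!r}, {b!r}) is not in the relation")
        ia, ib = self.universe.option_index(a), self.universe.option_index(b)
        j = self.universe.pair_index(ia, ib)
        return Relation(self.universe, self.mask ^ (1 << j))

    def adjacency(self) -> np.ndarray:
        """Boolean adjacency matrix M with M[i, k] = 1 iff option i beats k."""
        n = self.universe.n_options
        m = np.zeros((n, n), dtype=bool)
        for j, (i, k) in enumerate(self.universe.pairs):
            if (self.mask >> j) & 1:
                m[k, i] = True
            else:
                m[i, k] = True
        return m

    def is_transitive(self) -> bool:
        """True iff (a,b) and (b,c) in R imply (a,c) in R for all triples."""
        m = self.adjacency()
        closure = m @ m
        return not np.any(closure & ~m)

    def is_linear_order(self) -> bool:
        return self.is_transitive()

    def ranking(self) -> tuple[int, ...]:
        """Option indices from most to least preferred.

        Only meaningful for strict linear orders, where the out-degree
        sequence is a permutation of 0..n−1.
        """
        m = self.adjacency()
        outdeg = m.sum(axis=1)
        order = np.argsort(-outdeg, kind="stable")
        if sorted(outdeg) != list(range(len(outdeg))):
            raise ValueError("relation is not a strict linear order")
        return tuple(int(i) for i in order)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        bits = "".join(str(b) for b in self.bits())
        return f"Relation({bits})"


def is_acyclic(pairs: Iterable[tuple], options: Sequence[str] | None = None) -> bool:
    """True iff the (possibly incomplete) set of ordered pairs has no directed cycle.

    Accepts ordered pairs of arbitrary hashable node labels; detection is a
    depth-first search over the induced digraph.
    """
    adj: dict = {}
    for a, b in pairs:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, [])
    WHITE, GREY, BLACK = 0, 1, 2
    color = {v: WHITE for v in adj}
    for root in adj:
        if color[root] != WHITE:
            continue
        stack = [(root, iter(adj[root]))]
        color[root] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == GREY:
                    return False
                if color[nxt] == WHITE:
                    color[nxt] = GREY
                    stack.append((nxt, iter(adj[nxt])))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
    return True


def perm_to_order(universe: PairUniverse, perm: Sequence[int]) -> Relation:
    """Map a permutation of option indices to its strict linear order.

    Earlier-listed options are preferred to later-listed ones, so the
    permutation ``(0, 2, 1, 3)`` yields the order in which option 0 beats
    everything, option 2 beats options 1 and 3, and so on.
    """
    n = universe.n_options
    if sorted(perm) != list(range(n)):
        raise ValueError("perm must be a permutation of all option indices")
    rank = {opt: r for r, opt in enumerate(perm)}
    mask = 0
    for j, (i, k) in enumerate(universe.pairs):
        if rank[i] > rank[k]:  # k preferred to i -> reversed orientation
            mask |= 1 << j
    return Relation(universe, mask)


def all_relations(universe: PairUniverse) -> Iterator[Relation]:
    """All 2^C(n,2) asymmetric complete relations (use only for small n)."""
    for mask in range(1 << universe.n_pairs):
        yield Relation(universe, mask)


def all_linear_orders(universe: PairUniverse) -> list[Relation]:
    """The n! strict linear orders, via permutations (feasible for small n)."""
    return [
        perm_to_order(universe, perm)
        for perm in itertools.permutations(range(universe.n_options))
    ]


@dataclass(frozen=True)
class PreferenceStructure:
    """A set of preference states, optionally with state probabilities π."""

    states: tuple[Relation, ...]
    probs: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate states in structure")
        if not self.states:
            raise ValueError("a preference structure is nonempty")
        if self.probs is not None:
            p = np.asarray(self.probs, dtype=float)
            if len(p) != len(self.states):
                raise ValueError("probs and states length mismatch")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("probs must be nonnegative and sum to 1")
            object.__setattr__(self, "probs", tuple(float(x) for x in p))

    @property
    def universe(self) -> PairUniverse:
        return self.states[0].universe

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[Relation]:
        return iter(self.states)

    def __contains__(self, rel: Relation) -> bool:
        return rel in set(self.states)

    def as_set(self) -> frozenset[Relation]:
        return frozenset(self.states)


@dataclass(frozen=True)
class TwoComponentDesign:
    """A product-order design: options are (v, w) level combinations.

    Levels are 1-based and ordered by increasing severity, so level 1 is
    the most preferred ("least severe") level of each component.  The
    pointwise (coordinate-wise) order ``P0`` prefers option (v, w) to
    (v', w') whenever v ≤ v' and w ≤ w' and the options differ; any
    relation satisfying the monotonicity axiom must contain ``P0``.
    Options serialize as ``"v:w"``.
    """

    v_levels: int
    w_levels: int
    universe: PairUniverse = field(init=False, compare=False)

    def __post_init__(self) -> None:
        if self.v_levels < 1 or self.w_levels < 1:
            raise ValueError("levels must be positive")
        opts = tuple(
            f"{v}:{w}"
            for v in range(1, self.v_levels + 1)
            for w in range(1, self.w_levels + 1)
        )
        object.__setattr__(self, "universe", PairUniverse(opts))

    def levels(self, option_index: int) -> tuple[int, int]:
        v, w = divmod(option_index, self.w_levels)
        return v + 1, w + 1

    def p0_pairs(self) -> frozenset[tuple[int, int]]:
        """The pointwise order as ordered option-index pairs (a strict partial order)."""
        out = []
        n = self.universe.n_options
        for i in range(n):
            vi, wi = self.levels(i)
            for k in range(n):
                if i == k:
                    continue
                vk, wk = self.levels(k)
                if vi <= vk and wi <= wk:
                    out.append((i, k))
        return frozenset(out)

    def p0_pair_mask(self) -> int:
        """Bit mask over unordered pairs that P0 makes comparable.

        Because options are listed lexicographically by (v, w), whenever a
        pair {i, k} with i < k is P0-comparable the preferred option is
        always ``i``; the monotonicity axiom therefore pins those bits to 0.
        """
        mask = 0
        for j, (i, k) in enumerate(self.universe.pairs):
            vi, wi = self.levels(i)
            vk, wk = self.levels(k)
            if vi <= vk and wi <= wk:
                mask |= 1 << j
        return mask

    def is_monotone_stimulus(self, i: int, k: int) -> bool:
        """True iff one option weakly dominates the other in both components.

        A stimulus is *non-monotone* exactly when the two options strictly
        conflict: one is strictly less severe on one component and strictly
        more severe on the other.
        """
        if i == k:
            raise ValueError("stimulus options must be distinct")
        vi, wi = self.levels(i)
        vk, wk = self.levels(k)
        return not ((vi < vk and wi > wk) or (vi > vk and wi < wk))

    def monotone_pair_mask(self) -> int:
        mask = 0
        for j, (i, k) in enumerate(self.universe.pairs):
            if self.is_monotone_stimulus(i, k):
                mask |= 1 << j
        return mask

    def satisfies_MA(self, rel: Relation) -> bool:
        """Monotonicity axiom: the relation contains the pointwise order."""
        if rel.universe != self.universe:
            raise ValueError("relation is not over the design universe")
        return (rel.mask & self.p0_pair_mask()) == 0


@dataclass(frozen=True)
class ConstraintSet:
    """The admissible class ℒ* of centroids: strict linear orders, possibly MA-constrained."""

    kind: str = "linear_orders"
    design: Optional[TwoComponentDesign] = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear_orders", "linear_orders_with_MA"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.kind == "linear_orders_with_MA" and self.design is None:
            raise ValueError("MA constraints require a TwoComponentDesign")

    def __contains__(self, rel: Relation) -> bool:
        if not rel.is_transitive():
            return False
        if self.kind == "linear_orders_with_MA":
            assert self.design is not None
            return self.design.satisfies_MA(rel)
        return True

    # -- moves inside the class -----------------------------------------

    def free_pairs(self, rel: Relation) -> list[tuple[str, str]]:
        """Ordered pairs (a, b) ∈ L whose flip L − (a, b) stays in the class.

        Uses the adjacency shortcut: flipping a pair of a strict linear
        order preserves transitivity iff the two options are consecutive in
        the ranking.  Under MA a pair fixed by the pointwise order is never
        free.  (The generic flip-and-test route is ``free_pairs_generic``;
        a test asserts the two agree.)
        """
        if rel not in self:
            raise ValueError("relation is not in the constraint set")
        opts = rel.universe.options
        ranking = rel.ranking()
        p0 = self.design.p0_pair_mask() if self.kind == "linear_orders_with_MA" else 0
        out = []
        for a_idx, b_idx in zip(ranking[:-1], ranking[1:]):
            j = rel.universe.pair_index(a_idx, b_idx)
            if p0 and (p0 >> j) & 1:
                continue
            out.append((opts[a_idx], opts[b_idx]))
        return out

    def free_pairs_generic(self, rel: Relation) -> list[tuple[str, str]]:
        """Reference implementation of free pairs by exhaustive flip-and-test."""
        if rel not in self:
            raise ValueError("relation is not in the constraint set")
        out = []
        for a, b in sorted(rel.to_pairs()):
            if rel.flip(a, b) in self:
                out.append((a, b))
        return out

    def neighbors(self, rel: Relation) -> set[Relation]:
        """All members of the class at canonical distance exactly 2."""
        return {rel.flip(a, b) for a, b in self.free_pairs(rel)}
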