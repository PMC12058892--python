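"""Synthetic FCPC data: random preference structures, uniform state
mixtures, and per-pair response inversion.

The generative design mirrors the simulation setup the clustering methods
are meant for.  A "true" preference structure is a set of ``c`` strict
linear orders: random permutations for one-component options, random
linear extensions of the pointwise order P0 for two-component options (so
every state satisfies the monotonicity axiom).  Each simulated respondent
draws a state uniformly (with replacement) and then reports it with noise:
if the state holds ``a`` over ``b``, the response inverts that pair with
probability β_ab, independently across pairs.  The β are drawn once per
ordered pair, uniformly within a fixed interval (lo, hi] ⊆ [0, .5], and
held constant across respondents and replicates of a condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .clustering import Dataset
from .relations import (
    PairUniverse,
    PreferenceStructure,
    Relation,
    TwoComponentDesign,
    perm_to_order,
)

__all__ = [
    "ErrorModel",
    "SimulationSpec",
    "SimulatedSample",
    "random_structure_one_component",
    "random_structure_two_component",
    "random_linear_extension",
    "sample_betas",
    "generate_dataset",
    "random_linear_orders",
    "random_relations",
    "simulate",
]


@dataclass(frozen=True)
class ErrorModel:
    """Per-ordered-pair inversion probabilities β.

    ``betas`` has shape (n_pairs, 2): column 0 is β for the reference
    orientation of each canonical pair, column 1 for the reversed one.
    β_ab and β_ba are independent parameters, as the error model indexes
    them separately.
    """

    universe: PairUniverse
    betas: tuple[tuple[float, float], ...]
    interval: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        if b.shape != (self.universe.n_pairs, 2):
            raise ValueError("betas must have shape (n_pairs, 2)")
        if np.any(b < 0) or np.any(b > 0.5):
            raise ValueError("all β must lie in [0, 0.5]")
        lo, hi = self.interval
        if hi > 0 and (np.any(b <= lo) or np.any(b > hi)):
            raise ValueError("β outside the declared interval (lo, hi]")
        object.__setattr__(
            self, "betas", tuple((float(x), float(y)) for x, y in b)
        )

    @classmethod
    def no_error(cls, universe: PairUniverse) -> "ErrorModel":
        return cls(universe, tuple((0.0, 0.0) for _ in range(universe.n_pairs)))

    def beta_array(self) -> np.ndarray:
        return np.asarray(self.betas, dtype=float)

    def beta(self, a: str, b: str) -> float:
        """β_ab: probability that a response inverts (a, b) when the state holds it."""
        ia, ib = self.universe.option_index(a), self.universe.option_index(b)
        j = self.universe.pair_index(ia, ib)
        return self.betas[j][1 if ia > ib else 0]


def sample_betas(
    universe: PairUniverse,
    interval: Optional[tuple[float, float]],
    rng: np.random.Generator,
) -> ErrorModel:
    """Draw β_ab and β_ba independently, uniformly in (lo, hi].

    ``interval=None`` (or ``(0, 0)``) is the no-error condition: all β = 0.
    """
    if interval is None or interval == (0.0, 0.0) or interval == (0, 0):
        return ErrorModel.no_error(universe)
    lo, hi = interval
    if not (0.0 <= lo < hi <= 0.5):
        raise ValueError("interval must satisfy 0 <= lo < hi <= 0.5")
    draws = hi - rng.random((universe.n_pairs, 2)) * (hi - lo)  # in (lo, hi]
    return ErrorModel(universe, tuple(map(tuple, draws)), (lo, hi))


def random_structure_one_component(
    c: int, n_options: int, rng: np.random.Generator, universe: Optional[PairUniverse] = None
) -> PreferenceStructure:
    """``c`` distinct strict linear orders from uniform random permutations.

    Duplicate draws are rejected and redrawn so the structure (a set) has
    cardinality exactly ``c``.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if universe is None:
        universe = PairUniverse(tuple(f"s{i+1}" for i in range(n_options)))
    cap = math.factorial(n_options) if n_options <= 20 else None
    if cap is not None and c > cap:
        raise ValueError(f"cannot draw {c} distinct linear orders on {n_options} options")
    states: list[Relation] = []
    seen: set[Relation] = set()
    while len(states) < c:
        rel = perm_to_order(universe, tuple(int(i) for i in rng.permutation(n_options)))
        if rel not in seen:
            seen.add(rel)
            states.append(rel)
    return PreferenceStructure(tuple(states))


def random_linear_extension(
    design: TwoComponentDesign, rng: np.random.Generator
) -> Relation:
    """A random strict linear order containing the pointwise order P0.

    Starting from P0, repeatedly pick uniformly at random one orientation
    of a currently incomparable pair whose addition keeps the relation
    transitive, add it, and drop both orientations of that pair from the
    incomparable set.  The output is a strict linear order satisfying the
    monotonicity axiom.  (Uniform choice among *currently addable* pairs
    does not induce the uniform distribution over linear extensions; it
    reproduces the stated sequential procedure.)
    """
    n = design.universe.n_options
    m = np.zeros((n, n), dtype=bool)
    for i, k in design.p0_pairs():
        m[i, k] = True

    def addable(i: int, j: int) -> bool:
        # With m transitive, m + (i,j) is transitive iff every predecessor
        # of i already dominates j and its successors, and i dominates
        # every successor of j.
        anc = m[:, i]
        dsc = m[j, :]
        if np.any(anc & ~m[:, j]):
            return False
        if np.any(dsc & ~m[i, :]):
            return False
        if np.any(anc) and np.any(dsc) and not m[np.ix_(anc, dsc)].all():
            return False
        return True

    incomparable = [
        (i, k) for i in range(n) for k in range(i + 1, n) if not m[i, k] and not m[k, i]
    ]
    while incomparable:
        candidates = []
        for i, k in incomparable:
            if addable(i, k):
                candidates.append((i, k))
            if addable(k, i):
                candidates.append((k, i))
        if not candidates:  # pragma: no cover - a linear extension always exists
            raise RuntimeError("no transitivity-preserving pair available")
        i, k = candidates[rng.integers(len(candidates))]
        m[i, k] = True
        key = (min(i, k), max(i, k))
        incomparable.remove(key)

    mask = 0
    for j, (i, k) in enumerate(design.universe.pairs):
        if m[k, i]:
            mask |= 1 << j
    return Relation(design.universe, mask)


def random_structure_two_component(
    c: int, design: TwoComponentDesign, rng: np.random.Generator, max_attempts: int = 10_000
) -> PreferenceStructure:
    """``c`` distinct random linear extensions of the pointwise order."""
    if c < 1:
        raise ValueError("c must be >= 1")
    states: list[Relation] = []
    seen: set[Relation] = set()
    attempts = 0
    while len(states) < c:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("could not draw enough distinct MA linear orders")
        rel = random_linear_extension(design, rng)
        if rel not in seen:
            seen.add(rel)
            states.append(rel)
    return PreferenceStructure(tuple(states))


@dataclass(frozen=True)
class SimulatedSample:
    """A generated data set plus its latent ground truth."""

    dataset: Dataset
    labels: tuple[int, ...]  # true state index per respondent
    respondent_patterns: tuple[Relation, ...]  # pre-aggregation responses


def generate_dataset(
    structure: PreferenceStructure,
    error: ErrorModel,
    n: int,
    rng: np.random.Generator,
) -> SimulatedSample:
    """Simulate ``n`` i.i.d. respondents: state ~ π (uniform by default),
    then independent per-pair inversion with the model's β."""
    if n < 1:
        raise ValueError("n must be >= 1")
    universe = structure.universe
    if error.universe != universe:
        raise ValueError("error model universe mismatch")
    c = len(structure)
    probs = np.asarray(structure.probs) if structure.probs is not None else None
    labels = rng.choice(c, size=n, p=probs)
    zbits = np.stack([s.bit_array() for s in structure.states])  # c × J
    betas = error.beta_array()
    state_bits = zbits[labels]  # n × J
    # inversion probability of each pair depends on the state's orientation
    flip_prob = np.where(state_bits == 0, betas[:, 0], betas[:, 1])
    flips = rng.random(flip_prob.shape) < flip_prob
    xbits = state_bits ^ flips
    weights = 1 << np.arange(universe.n_pairs, dtype=object)
    masks = (xbits.astype(object) * weights).sum(axis=1)
    patterns = tuple(Relation(universe, int(msk)) for msk in masks)
    dataset = Dataset.from_patterns(universe, patterns)
    return SimulatedSample(dataset, tuple(int(x) for x in labels), patterns)


def random_linear_orders(
    k: int,
    universe_or_design: Union[PairUniverse, TwoComponentDesign],
    rng: np.random.Generator,
) -> PreferenceStructure:
    """``k`` random admissible initial centroids for the k-orders methods.

    Random permutations on a plain universe; random linear extensions of P0
    on a two-component design (TCA requires initial centroids inside ℒ*).
    Duplicates are redrawn.
    """
    if isinstance(universe_or_design, TwoComponentDesign):
        return random_structure_two_component(k, universe_or_design, rng)
    return random_structure_one_component(
        k, universe_or_design.n_options, rng, universe=universe_or_design
    )


def random_relations(
    k: int, universe: PairUniverse, rng: np.random.Generator
) -> PreferenceStructure:
    """``k`` distinct arbitrary relations (k-modes may start anywhere in 2^Q)."""
    seen: set[int] = set()
    out: list[Relation] = []
    while len(out) < k:
        bits = rng.integers(0, 2, size=universe.n_pairs)
        mask = int(sum(int(b) << j for j, b in enumerate(bits)))
        if mask not in seen:
            seen.add(mask)
            out.append(Relation(universe, mask))
    return PreferenceStructure(tuple(out))


@dataclass(frozen=True)
class SimulationSpec:
    """One simulation condition: design, structure size, sample size, error."""

    design: Union[int, TwoComponentDesign]  # option count, or a product design
    c: int
    n: int
    interval: Optional[tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 1 or self.n < 1:
            raise ValueError("c and n must be >= 1")
        if self.interval is not None:
            lo, hi = self.interval
            if not (0.0 <= lo <= hi <= 0.5):
                raise ValueError("interval must be within [0, 0.5]")


def simulate(spec: SimulationSpec) -> tuple[PreferenceStructure, ErrorModel, SimulatedSample]:
    """Generate a full condition from a spec: structure, error model, sample.

    The master seed is split into independent streams for the structure,
    the β draws, and the respondents, so each piece is reproducible on its
    own.
    """
    root = np.random.SeedSequence(spec.seed)
    s_struct, s_beta, s_resp = (np.random.default_rng(s) for s in root.spawn(3))
    if isinstance(spec.design, TwoComponentDesign):
        structure = random_structure_two_component(spec.c, spec.design, s_struct)
        universe = spec.design.universe
    else:
        structure = random_structure_one_component(spec.c, spec.design, s_struct)
        universe = structure.universe
    error = sample_betas(universe, spec.interval, s_beta)
    sample = generate_dataset(structure, error, spec.n, s_resp)
    return structure, error, sample
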