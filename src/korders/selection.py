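"""Model selection: incremental extension and the cross-validated
max-distance criterion for choosing the structure cardinality.

The procedure grows a sequence of candidate structures of increasing size
on a training split (two thirds of the respondents), seeding each new run
with the previous solution plus one additional state, and selects the
candidate minimizing M = max{δ(𝒱, P̂), δ(P̂, 𝒱)}, where 𝒱 is the set of
distinct patterns of the evaluation split.  Two evaluation modes exist:
``"validation"`` scores candidates on the held-out third;
``"train"`` scores them on the training patterns themselves (the mode
used when data are simulated from a known structure and no held-out test
of the structure is needed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .clustering import (
    Cluster,
    Dataset,
    greedy_tca_adjust,
    kmodes_adjust,
    run_korders,
    tca_adjust,
)
from .evaluate import avg_min_discrepancy
from .relations import ConstraintSet, PreferenceStructure, Relation

__all__ = [
    "CandidateScore",
    "SelectionResult",
    "split_train_validation",
    "incremental_extension",
    "select_best",
    "model_select",
]


def split_train_validation(
    data: Dataset, rng: np.random.Generator
) -> tuple[Dataset, Dataset]:
    """Respondent-level random 2/3 : 1/3 split.

    Frequencies must be integral (they count respondents); they are
    re-aggregated on each side of the split.
    """
    freqs = np.asarray(data.freqs)
    if not np.allclose(freqs, np.round(freqs)):
        raise ValueError("respondent-level split needs integer frequencies")
    respondents: list[Relation] = []
    for pat, f in zip(data.patterns, freqs):
        respondents.extend([pat] * int(round(f)))
    n = len(respondents)
    if n < 3:
        raise ValueError("need at least 3 respondents to split")
    order = rng.permutation(n)
    n_train = (2 * n) // 3
    train = [respondents[i] for i in order[:n_train]]
    valid = [respondents[i] for i in order[n_train:]]
    return (
        Dataset.from_patterns(data.universe, train),
        Dataset.from_patterns(data.universe, valid),
    )


def _fit_single_centroid(
    train: Dataset,
    method: str,
    constraints: ConstraintSet,
    rng: np.random.Generator,
) -> Relation:
    """The cardinality-one solution: adjust one centroid on the full data."""
    freqs = np.asarray(train.freqs)
    cluster = Cluster(train.universe, train.patterns, tuple(freqs / freqs.sum()))
    p0_pairs: tuple[tuple[int, int], ...] = ()
    if constraints.kind == "linear_orders_with_MA":
        assert constraints.design is not None
        p0_pairs = tuple(sorted(constraints.design.p0_pairs()))
    if method == "kmodes":
        return kmodes_adjust(cluster, rng)
    greedy = greedy_tca_adjust(cluster, p0_pairs, constraints)
    if method == "greedy":
        return greedy
    return tca_adjust(greedy, cluster, constraints)


def _farthest_pattern(
    train: Dataset,
    structure: PreferenceStructure,
    constraints: ConstraintSet,
    exhausted: set[Relation],
) -> Optional[Relation]:
    """Farthest-first seeding: the train pattern at maximal minimum distance
    from the current structure, projected into the admissible class.

    Seeds already in the structure or previously tried without effect
    (``exhausted``) are skipped; returns None when no admissible new seed
    remains (the incremental extension is then exhausted).
    """
    current = set(structure.states)
    cmasks = [c.mask for c in structure.states]
    scored = sorted(
        (
            (-min(int(p.mask ^ cm).bit_count() for cm in cmasks), p.mask, p)
            for p in train.patterns
        ),
    )
    for _, _, pat in scored:
        if pat in constraints:
            candidate = pat
        else:
            singleton = Cluster(train.universe, (pat,), (1.0,))
            p0_pairs: tuple[tuple[int, int], ...] = ()
            if constraints.kind == "linear_orders_with_MA":
                assert constraints.design is not None
                p0_pairs = tuple(sorted(constraints.design.p0_pairs()))
            candidate = greedy_tca_adjust(singleton, p0_pairs, constraints)
        if candidate not in current and candidate not in exhausted:
            return candidate
    return None


def incremental_extension(
    train: Dataset,
    k_max: int,
    method: str = "tca",
    constraints: Optional[ConstraintSet] = None,
    rng: Optional[np.random.Generator] = None,
    max_stalls: int = 3,
) -> list[PreferenceStructure]:
    """Locally optimal structures of increasing size, one per k = 1..k_max.

    Each run past the first is seeded with the previous solution plus one
    new state chosen farthest-first from the training patterns.  A
    proposed state can merge back into an existing centroid during
    re-clustering; such seeds are remembered and skipped, and after
    ``max_stalls`` consecutive merge-backs the extension is considered
    exhausted.  Duplicate adjusted centroids merge (the structure is a
    set), so the k-th structure can have fewer than k states.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    constraints = constraints or ConstraintSet()
    rng = rng or np.random.default_rng()
    k_max = min(k_max, len(train.patterns))

    first = _fit_single_centroid(train, method, constraints, rng)
    result = run_korders(
        train, PreferenceStructure((first,)), method=method, constraints=constraints, rng=rng
    )
    structures = [result.centroids]
    exhausted: set[Relation] = set()
    stalls = 0
    while len(structures) < k_max and stalls < max_stalls:
        seed_state = _farthest_pattern(train, structures[-1], constraints, exhausted)
        if seed_state is None:
            break
        init = PreferenceStructure(structures[-1].states + (seed_state,))
        result = run_korders(
            train, init, method=method, constraints=constraints, rng=rng
        )
        if set(result.centroids.states) == set(structures[-1].states):
            # the new state merged away: remember the seed, try the next one
            exhausted.add(seed_state)
            stalls += 1
            continue
        stalls = 0
        structures.append(result.centroids)
    return structures


@dataclass(frozen=True)
class CandidateScore:
    partition: int
    k: int
    cardinality: int
    d_eval_to_structure: float  # δ(𝒱, P̂)
    d_structure_to_eval: float  # δ(P̂, 𝒱)

    @property
    def m(self) -> float:
        return max(self.d_eval_to_structure, self.d_structure_to_eval)


@dataclass(frozen=True)
class SelectionResult:
    best_structure: PreferenceStructure
    best_m: float
    per_candidate: tuple[CandidateScore, ...]
    n_partitions: int


def select_best(
    candidates: list[PreferenceStructure],
    evaluation: Dataset,
    partition: int = 0,
) -> SelectionResult:
    """Pick the candidate with the smallest M = max{δ(𝒱, P̂), δ(P̂, 𝒱)}.

    The evaluation set enters δ as its collection of *distinct* patterns.
    Ties in M go to the smallest cardinality (parsimony).
    """
    if not candidates:
        raise ValueError("no candidate structures")
    eval_patterns = list(evaluation.patterns)
    scores = []
    for k, structure in enumerate(candidates, start=1):
        d1 = avg_min_discrepancy(eval_patterns, structure)
        d2 = avg_min_discrepancy(structure, eval_patterns)
        scores.append(
            CandidateScore(partition, k, len(structure), d1, d2)
        )
    best = min(
        range(len(scores)),
        key=lambda i: (scores[i].m, scores[i].cardinality, scores[i].k),
    )
    return SelectionResult(
        best_structure=candidates[best],
        best_m=scores[best].m,
        per_candidate=tuple(scores),
        n_partitions=1,
    )


def model_select(
    data: Dataset,
    k_max: int,
    method: str = "tca",
    constraints: Optional[ConstraintSet] = None,
    n_partitions: int = 1,
    criterion: str = "validation",
    rng: Optional[np.random.Generator] = None,
) -> SelectionResult:
    """Full selection pipeline: repeated splits, incremental extension,
    max-distance criterion.

    ``criterion="validation"`` splits the sample, extracts on the training
    two-thirds and scores candidates against the held-out third;
    ``criterion="train"`` skips the split entirely — candidates are
    extracted from and scored on the full sample (the simulation-study
    mode, where the ground truth is known and no held-out validation of
    the structure is needed).
    """
    if criterion not in ("validation", "train"):
        raise ValueError(f"unknown criterion {criterion!r}")
    constraints = constraints or ConstraintSet()
    rng = rng or np.random.default_rng()
    if criterion == "train":
        n_partitions = 1
    all_scores: list[CandidateScore] = []
    best_structure: Optional[PreferenceStructure] = None
    best_key: Optional[tuple[float, int]] = None
    for part in range(n_partitions):
        if criterion == "train":
            train = evaluation = data
        else:
            train, evaluation = split_train_validation(data, rng)
        candidates = incremental_extension(train, k_max, method, constraints, rng)
        result = select_best(candidates, evaluation, partition=part)
        all_scores.extend(result.per_candidate)
        for score, structure in zip(result.per_candidate, candidates):
            key = (score.m, score.cardinality)
            if best_key is None or key < best_key:
                best_key = key
                best_structure = structure
    assert best_structure is not None and best_key is not None
    return SelectionResult(
        best_structure=best_structure,
        best_m=best_key[0],
        per_candidate=tuple(all_scores),
        n_partitions=n_partitions,
    )
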