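"""Performance indexes for extracted preference structures.

Two families of indexes compare an extracted structure P̂ against the true
structure P used to generate the data: the true-positive rate (share of
exactly-matching states) and the average minimum symmetric-difference
discrepancy δ, which is asymmetric.  A third statistic estimates how
coherently respondents follow the monotonicity axiom on the monotone
stimuli of a two-component design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .clustering import Dataset
from .relations import PreferenceStructure, Relation, TwoComponentDesign

__all__ = [
    "EvaluationReport",
    "tpr",
    "true_state_recovery",
    "avg_min_discrepancy",
    "ma_violation_rate",
    "evaluate_extraction",
]

Collection = Union[PreferenceStructure, Sequence[Relation]]


def _states(x: Collection) -> tuple[Relation, ...]:
    states = tuple(x)
    if not states:
        raise ValueError("empty collection of relations")
    return states


def tpr(extracted: Collection, truth: Collection) -> float:
    """True-positive rate |P̂ ∩ P| / |P̂|.

    The denominator is the cardinality of the *extracted* structure; state
    identity is exact (bitwise) equality.
    """
    ext, tru = _states(extracted), _states(truth)
    return len(set(ext) & set(tru)) / len(set(ext))


def true_state_recovery(extracted: Collection, truth: Collection) -> float:
    """Proportion of *true* states present in the extracted structure:
    |P̂ ∩ P| / |P|.

    This is the "proportion of true states that belongs to the extracted
    structure" reading of the true-positive rate, which is the relevant
    index when the extracted structure over-extracts (|P̂| > |P|)."""
    ext, tru = _states(extracted), _states(truth)
    return len(set(ext) & set(tru)) / len(set(tru))


def avg_min_discrepancy(a: Collection, b: Collection, half: bool = False) -> float:
    """Average minimum discrepancy δ(𝒜, ℬ) = (1/|𝒜|) Σ_A min_B |A Δ B|.

    Asymmetric; zero exactly when 𝒜 ⊆ ℬ.  Distances are canonical
    symmetric-difference counts over ordered pairs (twice the number of
    disagreeing stimuli); ``half=True`` divides by two to count stimuli
    instead.
    """
    sa, sb = _states(a), _states(b)
    amasks = np.array([r.mask for r in sa], dtype=object)
    bmasks = np.array([r.mask for r in sb], dtype=object)
    total = 0
    for am in amasks:
        total += min(int(am ^ bm).bit_count() for bm in bmasks)
    # popcount of the XOR is the Hamming distance; |A Δ B| doubles it
    delta = 2.0 * total / len(sa)
    return delta / 2.0 if half else delta


def ma_violation_rate(data: Dataset, design: TwoComponentDesign) -> float:
    """Estimated probability p̂ of responding coherently with the
    monotonicity axiom.

    For each respondent, the proportion p_s of monotone stimuli answered
    with the dominated option is computed; p̂ = 1 − mean(p_s) (weighted by
    pattern frequencies).  For lexicographically indexed options the
    monotone stimuli are exactly the pairs made comparable by the pointwise
    order, and the dominating option is always the lower-index one, so a
    violation is simply a reversed bit on such a pair.
    """
    if data.universe != design.universe:
        raise ValueError("dataset is not over the design universe")
    mono_mask = design.monotone_pair_mask()
    n_mono = mono_mask.bit_count()
    if n_mono == 0:
        raise ValueError("design has no monotone stimuli")
    freqs = np.asarray(data.freqs)
    viol = np.array(
        [(p.mask & mono_mask).bit_count() / n_mono for p in data.patterns]
    )
    return float(1.0 - (freqs * viol).sum() / freqs.sum())


@dataclass(frozen=True)
class EvaluationReport:
    """Summary comparison of an extracted structure with the truth."""

    tpr: float
    recovery: float
    delta_extracted_to_true: float
    delta_true_to_extracted: float
    extracted_cardinality: int


def evaluate_extraction(
    extracted: Collection, truth: Collection
) -> EvaluationReport:
    ext = _states(extracted)
    return EvaluationReport(
        tpr=tpr(extracted, truth),
        recovery=true_state_recovery(extracted, truth),
        delta_extracted_to_true=avg_min_discrepancy(extracted, truth),
        delta_true_to_extracted=avg_min_discrepancy(truth, extracted),
        extracted_cardinality=len(set(ext)),
    )
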