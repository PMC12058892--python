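"""Basic local independence model (BLIM) over a preference structure.

The extracted preference states are treated as the latent classes of a
restricted latent class model.  A respondent in state P answers each
stimulus independently: if P holds (a, b), the response contains (b, a)
with probability β_(a,b) (a "false reversal") and (a, b) otherwise.  In
the paired-comparison translation of the model the false-endorsement rate
of an ordered pair equals the false-reversal rate of its inverse,
η_(a,b) = β_(b,a), so there is exactly one error parameter per ordered
pair — two per stimulus — stored as an (n_pairs, 2) array alongside the
state probabilities π.

Estimation is maximum likelihood via EM on pattern frequencies, model
comparison by AIC/AICc, and absolute fit by a Pearson X² whose null
distribution comes from a parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .clustering import Dataset
from .relations import PreferenceStructure, Relation, TwoComponentDesign

__all__ = [
    "BlimParams",
    "BlimFit",
    "conditional_prob",
    "marginal_prob",
    "em_fit",
    "simulate_from_blim",
    "pearson_x2",
    "parametric_bootstrap_gof",
    "HealthEconomyAggregates",
    "health_economy_aggregates",
]

_EPS = 1e-6  # error rates above 1/2 would re-encode the state


@dataclass(frozen=True)
class BlimParams:
    """State probabilities π and per-ordered-pair error rates.

    ``errors[j][0]`` is the false-reversal probability of the reference
    orientation of canonical pair j, ``errors[j][1]`` that of the reversed
    orientation.  The coupling η_(a,b) = β_(b,a) is structural: the false
    endorsement of one orientation *is* the false reversal of the other.
    """

    structure: PreferenceStructure
    pi: tuple[float, ...]
    errors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.pi, dtype=float)
        if len(p) != len(self.structure):
            raise ValueError("pi length mismatch")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a probability distribution")
        e = np.asarray(self.errors, dtype=float)
        if e.shape != (self.structure.universe.n_pairs, 2):
            raise ValueError("errors must have shape (n_pairs, 2)")
        if np.any(e < 0) or np.any(e > 0.5):
            raise ValueError("error rates must lie in [0, 0.5]")

    @classmethod
    def uniform(
        cls, structure: PreferenceStructure, error: float = 0.1
    ) -> "BlimParams":
        k = len(structure)
        j = structure.universe.n_pairs
        return cls(
            structure,
            tuple([1.0 / k] * k),
            tuple([(error, error)] * j),
        )

    def pi_array(self) -> np.ndarray:
        return np.asarray(self.pi, dtype=float)

    def error_array(self) -> np.ndarray:
        return np.asarray(self.errors, dtype=float)

    def beta(self, a: str, b: str) -> float:
        """β_(a,b): P(response holds (b,a) | state holds (a,b))."""
        u = self.structure.universe
        ia, ib = u.option_index(a), u.option_index(b)
        j = u.pair_index(ia, ib)
        return self.errors[j][1 if ia > ib else 0]

    def eta(self, a: str, b: str) -> float:
        """η_(a,b): P(response holds (a,b) | state holds (b,a)) = β_(b,a)."""
        return self.beta(b, a)


def _cond_matrix(
    pattern_bits: np.ndarray, state_bits: np.ndarray, errors: np.ndarray
) -> np.ndarray:
    """P(X|K) for patterns × states, vectorized over pairs."""
    # error rate of each state at each pair, given the state's orientation
    k_err = np.take_along_axis(
        errors, state_bits.astype(np.intp).T, axis=1
    ).T  # states × pairs
    mismatch = pattern_bits[:, None, :] != state_bits[None, :, :]
    with np.errstate(divide="ignore"):
        log_e = np.log(np.clip(k_err, 1e-300, None))
        log_1me = np.log(np.clip(1.0 - k_err, 1e-300, None))
    logp = np.where(mismatch, log_e[None, :, :], log_1me[None, :, :]).sum(axis=2)
    return np.exp(logp)


def conditional_prob(pattern: Relation, state: Relation, params: BlimParams) -> float:
    """P(X | K): product over stimuli of the matching error factor."""
    pb = pattern.bit_array()[None, :]
    sb = state.bit_array()[None, :]
    return float(_cond_matrix(pb, sb, params.error_array())[0, 0])


def marginal_prob(pattern: Relation, params: BlimParams) -> float:
    """P(X) = Σ_K P(X|K) π_K, the mixture over preference states."""
    pb = pattern.bit_array()[None, :]
    sb = np.stack([s.bit_array() for s in params.structure.states])
    cond = _cond_matrix(pb, sb, params.error_array())
    return float((cond @ params.pi_array())[0])


@dataclass(frozen=True)
class BlimFit:
    """A fitted BLIM with its likelihood and information criteria."""

    params: BlimParams
    loglik: float
    n_free_params: int
    aic: float
    aicc: float
    em_iterations: int
    converged: bool


def _n_free_params(structure: PreferenceStructure) -> int:
    # (|P| - 1) mixture weights + one error rate per ordered pair
    return (len(structure) - 1) + 2 * structure.universe.n_pairs


def em_fit(
    data: Dataset,
    structure: PreferenceStructure,
    init: Optional[BlimParams] = None,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> BlimFit:
    """Maximum-likelihood estimation by expectation-maximization.

    E-step: posterior state memberships over the distinct observed
    patterns.  M-step: closed-form frequency-ratio updates for π and for
    the coupled pair error rates.  Error rates are kept inside
    [1e-6, 0.5 − 1e-6]; the run stops when the log-likelihood improves by
    less than ``tol`` and returns the best parameters seen.
    """
    if data.universe != structure.universe:
        raise ValueError("dataset and structure universes differ")
    xbits = data.bit_matrix().astype(np.uint8)
    zbits = np.stack([s.bit_array() for s in structure.states]).astype(np.uint8)
    freqs = np.asarray(data.freqs)
    n = freqs.sum()

    params = init or BlimParams.uniform(structure)
    pi = params.pi_array().copy()
    err = np.clip(params.error_array(), _EPS, 0.5 - _EPS)

    z0 = (zbits == 0).astype(float)  # states × pairs
    z1 = 1.0 - z0
    best: Optional[tuple[float, np.ndarray, np.ndarray]] = None
    prev_ll = -np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        cond = _cond_matrix(xbits, zbits, err)
        mix = cond * pi[None, :]
        px = mix.sum(axis=1)
        ll = float(freqs @ np.log(np.clip(px, 1e-300, None)))
        if best is None or ll > best[0]:
            best = (ll, pi.copy(), err.copy())
        if ll - prev_ll < tol and iterations > 1:
            converged = ll >= prev_ll - 1e-9
            break
        prev_ll = ll

        post = mix / np.clip(px, 1e-300, None)[:, None]  # patterns × states
        w = freqs[:, None] * post
        pi = w.sum(axis=0) / n
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()

        wk = w.sum(axis=0)  # expected respondents per state
        t_rev = w.T @ xbits  # states × pairs: weight on reversed responses
        t_ref = w.T @ (1 - xbits)
        # reference-orientation states observed reversed, and vice versa
        num0 = (t_rev * z0).sum(axis=0)
        den0 = wk @ z0
        num1 = (t_ref * z1).sum(axis=0)
        den1 = wk @ z1
        new_err = err.copy()
        ok0 = den0 > 0
        ok1 = den1 > 0
        new_err[ok0, 0] = num0[ok0] / den0[ok0]
        new_err[ok1, 1] = num1[ok1] / den1[ok1]
        err = np.clip(new_err, _EPS, 0.5 - _EPS)

    assert best is not None
    ll, pi, err = best
    k_free = _n_free_params(structure)
    aic = -2.0 * ll + 2.0 * k_free
    if n > k_free + 1:
        aicc = aic + 2.0 * k_free * (k_free + 1) / (n - k_free - 1)
    else:
        aicc = float("inf")
    fitted = BlimParams(
        structure,
        tuple(float(x) for x in pi),
        tuple((float(a), float(b)) for a, b in err),
    )
    return BlimFit(fitted, ll, k_free, aic, aicc, iterations, converged)


def simulate_from_blim(
    params: BlimParams, n: int, rng: np.random.Generator
) -> Dataset:
    """Draw ``n`` respondents from a fitted model (state ~ π, then errors)."""
    universe = params.structure.universe
    zbits = np.stack([s.bit_array() for s in params.structure.states])
    labels = rng.choice(len(params.structure), size=n, p=params.pi_array())
    state_bits = zbits[labels]
    err = params.error_array()
    flip_prob = np.where(state_bits == 0, err[:, 0], err[:, 1])
    xbits = state_bits ^ (rng.random(flip_prob.shape) < flip_prob)
    patterns = [
        Relation(universe, int(sum(int(b) << j for j, b in enumerate(row))))
        for row in xbits
    ]
    return Dataset.from_patterns(universe, patterns)


def pearson_x2(
    data: Dataset, params: BlimParams, cells: Sequence[Relation]
) -> float:
    """Pearson X² over the cell scheme: one cell per listed pattern plus a
    pooled cell for every other pattern."""
    n = sum(data.freqs)
    counts = {p: f for p, f in zip(data.patterns, data.freqs)}
    probs = np.array([marginal_prob(c, params) for c in cells])
    observed = np.array([counts.get(c, 0.0) for c in cells])
    pooled_p = max(1.0 - probs.sum(), 0.0)
    pooled_o = n - observed.sum()
    expected = n * probs
    x2 = float(((observed - expected) ** 2 / np.clip(expected, 1e-300, None)).sum())
    if pooled_p > 1e-12 or pooled_o > 0:
        x2 += (pooled_o - n * pooled_p) ** 2 / max(n * pooled_p, 1e-300)
    return x2


def parametric_bootstrap_gof(
    fit: BlimFit,
    data: Dataset,
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
    em_tol: float = 1e-6,
    em_max_iter: int = 500,
) -> tuple[float, float, np.ndarray]:
    """Parametric-bootstrap p value for the Pearson X² statistic.

    Simulates ``n_boot`` data sets of the observed size from the fitted
    model, refits each, and recomputes X² under the *same cell rule* as
    the observed statistic: each data set is scored on its own distinct
    observed patterns plus one pooled "all other patterns" cell.  (Scoring
    replicates on the original data's cell list would break
    exchangeability — the observed pooled cell is empty by construction.)
    Returns ``(p_value, observed_x2, bootstrap_x2s)`` with
    p = fraction of bootstrap statistics ≥ the observed one.
    """
    rng = rng or np.random.default_rng()
    obs_x2 = pearson_x2(data, fit.params, list(data.patterns))
    n = int(round(sum(data.freqs)))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        sim = simulate_from_blim(fit.params, n, rng)
        refit = em_fit(
            sim, fit.params.structure, init=fit.params, tol=em_tol, max_iter=em_max_iter
        )
        boot[b] = pearson_x2(sim, refit.params, list(sim.patterns))
    p = float((boot >= obs_x2).mean())
    return p, obs_x2, boot


@dataclass(frozen=True)
class HealthEconomyAggregates:
    """Per-state counts over non-monotone stimuli and class probabilities.

    ``counts[s]`` is |P_Hc|, the number of non-monotone stimuli the state
    resolves in favor of the lower-severity *second-component* option
    (health, under the economy-first labeling convention).
    """

    counts: tuple[int, ...]
    n_non_monotone: int
    p_health: float
    p_economy: float
    p_equal: float


def health_economy_aggregates(
    structure: PreferenceStructure,
    pi: Sequence[float],
    design: TwoComponentDesign,
) -> HealthEconomyAggregates:
    """Partition states by which component they favor on the conflict stimuli.

    Options are (economy, health) level pairs; a non-monotone stimulus
    opposes a lower-economy-severity option to a lower-health-severity one.
    A state with |P_Hc| > |P_Ec| favors health; summing π inside each class
    gives the aggregate probabilities P_H and P_E (ties form the
    equal-weight class).
    """
    if structure.universe != design.universe:
        raise ValueError("structure is not over the design universe")
    p = np.asarray(pi, dtype=float)
    if len(p) != len(structure):
        raise ValueError("pi length mismatch")
    non_mono = ~np.array(
        [design.is_monotone_stimulus(i, k) for (i, k) in design.universe.pairs]
    )
    n_nm = int(non_mono.sum())
    # for a non-monotone pair {i, k} with i < k, option k has the lower
    # health severity, so the reversed orientation (bit 1) is the health choice
    counts = []
    for s in structure.states:
        bits = s.bit_array().astype(bool)
        counts.append(int((bits & non_mono).sum()))
    counts_arr = np.array(counts)
    p_health = float(p[counts_arr > n_nm - counts_arr].sum())
    p_economy = float(p[counts_arr < n_nm - counts_arr].sum())
    p_equal = float(p[counts_arr == n_nm - counts_arr].sum())
    return HealthEconomyAggregates(
        counts=tuple(counts),
        n_non_monotone=n_nm,
        p_health=p_health,
        p_economy=p_economy,
        p_equal=p_equal,
    )
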