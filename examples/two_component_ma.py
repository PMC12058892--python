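"""Two-component options and the monotonicity axiom.

Options are (economy, health) severity-level pairs on a 4x4 grid: 120
stimuli, of which 84 are monotone (one option dominates componentwise)
and 36 oppose the two components.  States are random linear extensions of
the pointwise order, so every simulated respondent is MA-consistent up to
response error; clustering under MA constraints returns centroids that
contain the pointwise order by construction.
"""

import numpy as np

from korders import (
    ConstraintSet,
    TwoComponentDesign,
    avg_min_discrepancy,
    generate_dataset,
    ma_violation_rate,
    random_linear_orders,
    random_structure_two_component,
    run_korders,
    sample_betas,
)

design = TwoComponentDesign(4, 4)
mono = design.monotone_pair_mask().bit_count()
print(f"4x4 design: {design.universe.n_pairs} stimuli, "
      f"{mono} monotone, {design.universe.n_pairs - mono} non-monotone")

rng = np.random.default_rng(3)
truth = random_structure_two_component(10, design, rng)
betas = sample_betas(design.universe, (0.0, 0.05), rng)
sample = generate_dataset(truth, betas, n=400, rng=rng)

p_hat = ma_violation_rate(sample.dataset, design)
print(f"estimated probability of MA-coherent responses: p_hat = {p_hat:.3f}")

constraints = ConstraintSet("linear_orders_with_MA", design)
init = random_linear_orders(10, design, rng)
result = run_korders(sample.dataset, init, method="tca",
                     constraints=constraints, rng=rng)
delta = avg_min_discrepancy(result.centroids, truth)
ma_ok = all(design.satisfies_MA(c) for c in result.centroids)
print(f"TCA under MA: {len(result.centroids)} centroids, "
      f"delta(extracted, true) = {delta:.2f}, all satisfy MA: {ma_ok}")
print("p_hat near 1 says respondents almost never pick a dominated option; "
      "delta near 0 says the extracted orders match the generating states.")
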