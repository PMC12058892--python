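"""Simulate a one-component paired-comparison study and compare the three
clustering methods.

Ten options, fifty true preference states, 500 respondents, per-pair
inversion probabilities drawn in (.20, .30] — a heterogeneous, noisy
population where the transitivity constraint matters.  Each method
extracts a structure from the same data; delta(extracted, true) is the
average minimum symmetric-difference distance from an extracted state to
the truth (0 = every extracted state is a true state), and recovery is
the share of true states found exactly.
"""

import numpy as np

from korders import (
    avg_min_discrepancy,
    generate_dataset,
    random_linear_orders,
    random_relations,
    random_structure_one_component,
    run_korders,
    sample_betas,
    true_state_recovery,
)

rng = np.random.default_rng(7)
truth = random_structure_one_component(c=50, n_options=10, rng=rng)
betas = sample_betas(truth.universe, (0.20, 0.30), rng)
sample = generate_dataset(truth, betas, n=500, rng=rng)

init_orders = random_linear_orders(50, truth.universe, rng)
init_any = random_relations(50, truth.universe, rng)

print(f"{len(sample.dataset.patterns)} distinct patterns from 500 respondents\n")
for method, init in (("kmodes", init_any), ("tca", init_orders), ("greedy", init_orders)):
    result = run_korders(sample.dataset, init, method=method,
                         rng=np.random.default_rng(7))
    delta = avg_min_discrepancy(result.centroids, truth)
    rec = true_state_recovery(result.centroids, truth)
    transitive = all(c.is_transitive() for c in result.centroids)
    print(f"{method:7s} delta(extracted, true) = {delta:5.2f}   "
          f"recovery = {rec:.2f}   all centroids transitive: {transitive}")
print("\nLower delta means extracted states sit closer to the true ones; "
      "only the k-orders variants guarantee transitive centroids.")
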