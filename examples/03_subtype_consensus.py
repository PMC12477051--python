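"""Classify samples into molecular subtypes by NMF and build the consensus.

Three signature schemes (k = 2, 3, 4 subtypes) are each clustered by NMF on
their signature-gene submatrix; a sample called unfavourable by at least 3
schemes is consensus-aggressive.  The association of the High/Low score
groups with the consensus flag is tested with a chi-squared test.
"""

import pandas as pd

from aldhnet.network import default_network, derive_coefficients
from aldhnet.scoring import compute_scores
from aldhnet.simulate import CohortSpec, simulate_cohort
from aldhnet.subtypes import (
    association_tests,
    classify_scheme,
    consensus_aggressive,
    default_schemes,
)

expr, truth = simulate_cohort(CohortSpec(n_samples=200, seed=1))
schemes = default_schemes()
calls = pd.DataFrame({s.name: classify_scheme(expr, s, seed=1) for s in schemes})
cons = consensus_aggressive(calls, schemes, threshold=3)

agree = (cons["consensus_aggressive"] == (truth == "basal-like")).mean()
print(f"consensus-aggressive samples: {int(cons['consensus_aggressive'].sum())}"
      f" / {len(cons)}")
print(f"agreement with planted basal-like truth: {100 * agree:.1f} %")

scores = compute_scores(expr, derive_coefficients(default_network()))
assoc = association_tests(scores["group"], cons["consensus_aggressive"],
                          scores["score"])
print(f"High/Low vs aggressive 2x2 table: {assoc['table'].tolist()}")
print(f"{assoc['test']} p = {assoc['p']:.3g}; Welch t-test on scores "
      f"p = {assoc['t_p']:.3g}")
print("A small p-value means the High-score group is enriched for samples "
      "that several classification schemes independently call aggressive.")
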