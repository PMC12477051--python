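"""Compare survival between High and Low score groups.

Event times are simulated from an exponential model in which the planted
basal-like samples carry a higher hazard; Kaplan-Meier curves per score
group are compared with the log-rank test.
"""

from aldhnet.network import default_network, derive_coefficients
from aldhnet.scoring import compute_scores
from aldhnet.simulate import CohortSpec, SurvivalSpec, simulate_cohort, simulate_survival
from aldhnet.survival import km_estimate, logrank_test

expr, truth = simulate_cohort(CohortSpec(n_samples=200, seed=1))
clinical = simulate_survival((truth == "basal-like").astype(int),
                             SurvivalSpec(hazard_ratio=2.5, seed=2))

scores = compute_scores(expr, derive_coefficients(default_network()))
clinical = clinical.drop(columns="group").join(scores["group"])

for grp in ("High", "Low"):
    km = km_estimate(clinical, grp)
    median_t = km.loc[km["survival"] <= 0.5, "time"].min()
    print(f"{grp:4s} group: n = {(clinical['group'] == grp).sum()}, "
          f"median survival ~ {median_t:.1f} time units")

res = logrank_test(clinical)
print(f"log-rank chi-squared = {res['statistic']:.2f}, p = {res['p']:.3g}")
print("The High-score group reaches 50% survival sooner: the network score "
      "stratifies the simulated cohort by outcome.")
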