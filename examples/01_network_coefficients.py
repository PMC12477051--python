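"""Derive the per-gene scoring coefficients from network connectivity.

Each of the 8 genes carries a weight counting its share of the 13 network
edges (a bidirectional edge splits one unit between its endpoints, a
directed edge gives half a unit to its target); normalising by the total
yields the percentage coefficient each gene contributes to the score.
"""

from aldhnet.network import default_network, derive_coefficients

net = default_network()
coeffs = derive_coefficients(net)

print(f"total network weight: {net.total_weight:g} (one unit per edge, 13 edges)")
for gene in net.genes:
    print(f"  {gene:8s} weight {net.gene_weights[gene]:>3g}  ->  "
          f"{coeffs.percent[gene]:6.2f} %")
print("A gene's percentage is its connectivity share: ALDH1A3, the hub, "
      "carries the largest weight in the score.")
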