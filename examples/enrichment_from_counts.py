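"""Protease enrichment statistics from a published count table.

Given per-protease counts — k termini in the experiment's list out of n
cleavage-derived termini, against K known database cleavage sites out of M
on the list's proteins — compute fold enrichment (k/n)/(K/M), fold
coverage k/K, the one-sided Fisher exact p-value and the BH q-value.
A q-value below 0.05 flags a protease whose known sites are
over-represented in the list beyond what its database coverage predicts.
"""

from termikit import bh_adjust, fisher_enrichment_p

n, M = 129, 1265
counts = [("MMP2", 68, 537), ("GRAB", 16, 58), ("CASP3", 7, 28),
          ("MPPB", 4, 4), ("THRB", 1, 1)]

p_values = [fisher_enrichment_p(k, n, K, M) for _, k, K in counts]
q_values = bh_adjust(p_values)

print(f"{'protease':<10}{'k':>4}{'K':>6}{'fold_enr':>10}{'coverage':>10}"
      f"{'p':>12}{'q':>12}")
for (name, k, K), p, q in zip(counts, p_values, q_values):
    print(f"{name:<10}{k:>4}{K:>6}{(k / n) / (K / M):>10.2f}{k / K:>10.2f}"
          f"{p:>12.2E}{q:>12.2E}")
print("\nMPPB: all 4 of its known sites appear among the 129 cleaved "
      "termini -> strong enrichment despite small counts.")
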