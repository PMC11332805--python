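"""Rank codons by how widely their usage varies across a collection.

Simulates a 150-genome collection spanning a wide GC range and computes, for
every codon, the standard deviation of usage and Delta 90-10 (the distance
between the 90th and 10th percentiles) — the two range statistics that
separate "variable" from "low-variability" codons.
"""

from codonvar import default_config, simulate_collection, variability_table

col = simulate_collection(default_config(n_genomes=150, seed=2))
table = variability_table(col.usage, thresholds=(1.0, 3.0))

ranked = table.sort_values("delta_90_10")
print("least variable codons (narrow usage range):")
print(ranked[["sd", "p10", "p90", "delta_90_10", "label"]].head(5).round(3))
print()
print("most variable codons (wide usage range):")
print(ranked[["sd", "p10", "p90", "delta_90_10", "label"]].tail(5).round(3))
print()
flat = col.beta[col.beta == 0].index
print(
    f"mean delta of beta=0 codons: "
    f"{table.loc[flat, 'delta_90_10'].mean():.2f} pp vs all codons: "
    f"{table['delta_90_10'].mean():.2f} pp"
)
print(
    "\nDelta 90-10 is in percentage points of usage. Codons built to ignore\n"
    "GC pressure (beta = 0) occupy a much narrower range than responsive ones."
)
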