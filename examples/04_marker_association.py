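"""Test codon-usage and GC differences between marker-defined genome groups.

Splits a simulated collection by presence/absence of marker genes (standing
in for tRNA-modification genes) and applies the rank-based battery: a
two-sided Wilcoxon-Mann-Whitney test per codon at alpha = 5e-5, and for the
two GC-linked markers the four-group Kruskal-Wallis + Dunn + Holm design.
"""

from codonvar import compare_all, default_config, four_group_gc, simulate_collection

col = simulate_collection(default_config(n_genomes=300, seed=4))

res = compare_all(
    col.usage[["AAA", "AAG", "GAC", "GAT", "GGC"]],
    col.presence,
    markers=["tusE_motif3", "gluQRS_motif3"],
)
print("two-group rank-sum tests (alpha = 0.00005):")
print(res[["marker", "response", "median_present", "median_absent",
           "p_two_sided", "significant"]].round(4).to_string(index=False))

g4 = four_group_gc(col.gc, col.presence, "tsaB_motif1", "gluQRS_motif3")
print(f"\nfour-group GC comparison: Kruskal-Wallis H = {g4.kw_h:.1f}, "
      f"p = {g4.kw_p:.2e}")
print("group medians:", {k: round(v, 3) for k, v in g4.group_medians.items()})
print(g4.pairs.round(4).to_string(index=False))
print(
    "\nThe marker that doubles AAA weight is detected on AAA/AAG but not on\n"
    "unrelated codons; genomes lacking both GC-linked markers have the\n"
    "lowest GC, and Holm-adjusted pairwise tests flag the separated groups."
)
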