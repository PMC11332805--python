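"""Relate codon usage to tRNA gene counts from tRNAscan-SE output.

Writes synthetic tRNAscan-SE 2.0 tabular files (with an initiator tRNA-Met
row that the counting stage must exclude), parses them back, counts genes
per anticodon, and correlates each codon's usage with the gene count of its
decoding anticodons under strict Watson-Crick pairing and with the classical
wobble rules.
"""

import tempfile
from pathlib import Path

from codonvar import (
    count_anticodons,
    default_config,
    parse_trnascan,
    simulate_collection,
    usage_vs_counts,
)
from codonvar.simulate import emit_trnascan_fixture

col = simulate_collection(default_config(n_genomes=25, genes_per_genome=40, seed=5))

with tempfile.TemporaryDirectory() as tmp:
    paths = emit_trnascan_fixture(col.usage, Path(tmp), rule="usage_tied", scale=4.0)
    genes = []
    for p in paths:
        genes.extend(parse_trnascan(p, genome_id=p.stem.split(".")[0]))

counts = count_anticodons(genes)  # initiator tRNA-Met excluded here
print(f"parsed {len(genes)} tRNA genes -> count table {counts.shape}")

for pairing in ("perfect_only", "perfect_plus_wobble"):
    corr = usage_vs_counts(col.usage, counts, pairing)
    top = corr["spearman_rho"].dropna().sort_values()
    print(f"\n{pairing}: median Spearman rho = {top.median():.2f} "
          f"(AAC: {corr.loc['AAC', 'spearman_rho']:.2f})")

print(
    "\nGene counts here were tied monotonically to usage, so correlations\n"
    "are strongly positive — the positive control. With rule='constant'\n"
    "they are absent, the negative control."
)
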