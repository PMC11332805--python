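from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from codonvar.codes import CODONS
from codonvar.io import CDSFeature, GenomeAssembly
from codonvar.usage import (
    DEFAULT_HEG_CATALOG,
    build_usage_matrix,
    filter_genes,
    gc_fraction,
    gene_codon_frequencies,
    genome_mean_usage,
    genome_profile,
    select_heg,
)
from conftest import random_coding_sequence


def naive_frequencies(sequence: str) -> dict:
    """Independent oracle: plain-Python triplet tally with the skip rule."""
    triplets = [sequence[i : i + 3] for i in range(0, len(sequence), 3)]
    counted = [t for t in triplets if all(b in "ACGT" for b in t)]
    tally = Counter(counted)
    return {c: 100.0 * tally.get(c, 0) / len(counted) for c in CODONS}


def _cds(seq, id="x", pseudo=False, gene="", product=""):
    return CDSFeature(id=id, sequence=seq, pseudo=pseudo,
                      gene_symbol=gene, product=product)


class TestFilterGenes:
    def test_pseudo_and_length_reasons(self):
        genes = [_cds("ATGAAATAA", "a"), _cds("ATGAAATA", "b"),
                 _cds("ATGAAATAA", "c", pseudo=True)]
        kept, excluded = filter_genes(genes)
        assert [f.id for f in kept] == ["a"]
        assert {(f.id, r) for f, r in excluded} == {("b", "length"), ("c", "pseudo")}

    def test_all_valid_and_empty(self):
        genes = [_cds("ATGTAA", "a")]
        assert filter_genes(genes) == (genes, [])
        assert filter_genes([]) == ([], [])


class TestGeneCodonFrequencies:
    def test_hand_counted_example(self):
        v = gene_codon_frequencies("ATGAAAAAATAA")
        assert v["ATG"] == 25.0 and v["AAA"] == 50.0 and v["TAA"] == 25.0
        assert v.drop(["ATG", "AAA", "TAA"]).eq(0).all()

    def test_ambiguous_triplet_skipped_from_denominator(self):
        v = gene_codon_frequencies("ATGNNNAAA")
        assert v["ATG"] == 50.0 and v["AAA"] == 50.0

    def test_bad_length_and_all_ambiguous(self):
        with pytest.raises(ValueError, match="divisible"):
            gene_codon_frequencies("ATGA")
        with pytest.raises(ValueError, match="no countable"):
            gene_codon_frequencies("NNNNNN")

    def test_matches_naive_oracle_on_random_sequences(self, rng):
        for _ in range(200):
            seq = random_coding_sequence(rng, int(rng.integers(1, 301)),
                                         ambiguous_rate=0.02)
            if all(any(b == "N" for b in seq[i:i + 3])
                   for i in range(0, len(seq), 3)):
                continue
            got = gene_codon_frequencies(seq)
            expected = naive_frequencies(seq)
            np.testing.assert_allclose(got.to_numpy(),
                                       [expected[c] for c in CODONS], atol=1e-9)

    @given(st.integers(min_value=1, max_value=200), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_vector_sums_to_100(self, n_codons, seed):
        seq = random_coding_sequence(np.random.default_rng(seed), n_codons)
        assert gene_codon_frequencies(seq).sum() == pytest.approx(100.0, abs=1e-6)


class TestGenomeMeanUsage:
    def test_mean_of_two_vectors(self):
        v1 = gene_codon_frequencies("ATGAAAAAATAA")
        v2 = gene_codon_frequencies("ATGATGTAATAA")
        m = genome_mean_usage([v1, v2])
        assert m["ATG"] == pytest.approx(37.5)
        assert m["AAA"] == pytest.approx(25.0)
        assert m["TAA"] == pytest.approx(37.5)

    def test_single_vector_identity_and_empty_error(self):
        v = gene_codon_frequencies("ATGTAA")
        pd.testing.assert_series_equal(genome_mean_usage([v]), v, check_names=False)
        with pytest.raises(ValueError, match="no genes"):
            genome_mean_usage([])

    def test_matches_extended_precision_oracle(self, rng):
        raw = rng.random((100, 64))
        vectors = [pd.Series(100 * r / r.sum(), index=list(CODONS)) for r in raw]
        got = genome_mean_usage(vectors)
        oracle = np.mean(
            np.stack([v.to_numpy(dtype=np.longdouble) for v in vectors]), axis=0
        )
        np.testing.assert_allclose(got.to_numpy(), oracle.astype(float), atol=1e-9)


class TestSelectHeg:
    def test_symbol_and_product_matching(self):
        genes = [
            _cds("ATGTAA", "a", gene="tuf"),
            _cds("ATGTAA", "b", gene="fusA"),
            _cds("ATGTAA", "c", product="DNA-directed RNA polymerase subunit beta"),
            _cds("ATGTAA", "d", product="hypothetical protein"),
        ]
        heg, found, missing = select_heg(genes)
        assert {f.id for f in heg} == {"a", "b", "c"}
        assert found == {"EF-Tu", "EF-G", "RpoB"}
        assert len(missing) == 10

    def test_multicopy_tuf_genes_all_returned(self):
        genes = [_cds("ATGTAA", "a", gene="tufA"), _cds("ATGTAA", "b", gene="tufB")]
        heg, found, _ = select_heg(genes)
        assert len(heg) == 2 and found == {"EF-Tu"}

    def test_no_matches_error(self):
        with pytest.raises(ValueError, match="no HEG"):
            select_heg([_cds("ATGTAA", "a")])


class TestGcFraction:
    def test_hand_counted(self):
        assert gc_fraction("GGCCAATT") == 0.5
        assert gc_fraction("GCGC") == 1.0

    def test_plasmid_included(self):
        asm = GenomeAssembly("g", replicons=[("chr", "AT"), ("plasmid", "GC")])
        assert gc_fraction(asm) == 0.5

    def test_ambiguity_excluded_and_empty_error(self):
        assert gc_fraction("GCNN") == 1.0
        with pytest.raises(ValueError):
            gc_fraction("NNNN")

    def test_complement_swap_symmetry(self, rng):
        seq = random_coding_sequence(rng, 200)
        swapped = seq.translate(str.maketrans("AGTC", "GACT"))
        assert gc_fraction(seq) == pytest.approx(1 - gc_fraction(swapped))


def _toy_assembly(genome_id="g1", n_genes=5, seed=0):
    rng = np.random.default_rng(seed)
    cds = [
        _cds(random_coding_sequence(rng, 50), f"{genome_id}_g{i}",
             gene="tuf" if i == 0 else "")
        for i in range(n_genes)
    ]
    return GenomeAssembly(
        genome_id, replicons=[(genome_id, "".join(f.sequence for f in cds))], cds=cds
    )


class TestGenomeProfile:
    def test_gene_order_permutation_invariant(self):
        asm = _toy_assembly()
        shuffled = GenomeAssembly(asm.genome_id, asm.replicons, asm.cds[::-1])
        p1, p2 = genome_profile(asm), genome_profile(shuffled)
        np.testing.assert_allclose(p1.usage_all, p2.usage_all)

    def test_duplicating_every_gene_leaves_mean_unchanged(self):
        asm = _toy_assembly()
        doubled_cds = asm.cds + [
            _cds(f.sequence, f.id + "_copy", gene=f.gene_symbol) for f in asm.cds
        ]
        doubled = GenomeAssembly(asm.genome_id, asm.replicons, doubled_cds)
        np.testing.assert_allclose(
            genome_profile(asm).usage_all, genome_profile(doubled).usage_all
        )

    def test_exclude_stops_renormalizes(self):
        asm = _toy_assembly()
        p = genome_profile(asm, exclude_stops=True)
        assert p.usage_all[["TAA", "TAG", "TGA"]].eq(0).all()
        assert p.usage_all.sum() == pytest.approx(100.0, abs=1e-6)

    def test_weighted_mean_differs_for_unequal_lengths(self):
        rng = np.random.default_rng(1)
        cds = [_cds(random_coding_sequence(rng, 10), "a", gene="tuf"),
               _cds(random_coding_sequence(rng, 500), "b")]
        asm = GenomeAssembly("g", [("g", "".join(f.sequence for f in cds))], cds)
        un = genome_profile(asm).usage_all
        w = genome_profile(asm, weighted=True).usage_all
        assert not np.allclose(un, w)
        assert w.sum() == pytest.approx(100.0, abs=1e-6)


class TestBuildUsageMatrix:
    def test_rows_sum_to_100(self):
        profiles = [genome_profile(_toy_assembly(f"g{i}", seed=i)) for i in range(3)]
        m = build_usage_matrix(profiles, "all")
        assert m.shape == (3, 64)
        np.testing.assert_allclose(m.sum(axis=1), 100.0, atol=1e-6)

    def test_heg_subset_drops_profiles_without_heg(self):
        p1 = genome_profile(_toy_assembly("g1"))
        p2 = genome_profile(_toy_assembly("g2"))
        p2.usage_heg = None
        m = build_usage_matrix([p1, p2], "heg")
        assert list(m.index) == ["g1"]

    def test_duplicate_genome_id_rejected(self):
        p = genome_profile(_toy_assembly("g1"))
        with pytest.raises(ValueError, match="duplicate"):
            build_usage_matrix([p, p], "all")
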