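"""Genetic-code tables and codon string helpers.

Everything downstream indexes codons by their position in :data:`CODONS`,
the 64 DNA triplets in lexicographic A<C<G<T order.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

#: The 64 DNA triplets, lexicographic order; fixed column order of every matrix.
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: Standard (translation table 11) codon -> one-letter amino acid, '*' = stop.
GENETIC_CODE: dict[str, str] = {}
_AA_BY_BLOCK = (
    "KNKN" "TTTT" "RSRS" "IIMI"  # AAx ACx AGx ATx
    "QHQH" "PPPP" "RRRR" "LLLL"  # CAx CCx CGx CTx
    "EDED" "AAAA" "GGGG" "VVVV"  # GAx GCx GGx GTx
    "*Y*Y" "SSSS" "*CWC" "LFLF"  # TAx TCx TGx TTx
)
for _i, _codon in enumerate(CODONS):
    GENETIC_CODE[_codon] = _AA_BY_BLOCK[_i]

STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

#: Synonymous families of the standard code: amino acid -> tuple of codons.
#: Stops are kept as their own family under the key '*'.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in GENETIC_CODE.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes pass through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_count(codon: str) -> int:
    """Number of G or C letters in a triplet (0-3)."""
    return sum(1 for b in codon if b in "GC")


def third_base(codon: str) -> str:
    """Wobble-position (third) base of a codon."""
    return codon[2]


#: Per-codon G+C letter counts aligned with CODONS, for vectorized GC math.
CODON_GC_COUNTS: np.ndarray = np.array([gc_count(c) for c in CODONS])

IS_STOP: np.ndarray = np.array([c in STOP_CODONS for c in CODONS])
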