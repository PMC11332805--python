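"""Per-gene and per-genome codon-usage frequency vectors.

The statistic throughout is the *frequency of usage*: the percentage of a
gene's codons equal to each triplet (stop codon included by default), then
averaged over genes with equal weight to give the genome's usage vector.
This is deliberately not codon usage *bias* — no within-amino-acid
normalization is applied anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import CODONS, CODON_INDEX
from .io import CDSFeature, GenomeAssembly

log = logging.getLogger(__name__)

__all__ = [
    "HEGCatalog",
    "DEFAULT_HEG_CATALOG",
    "GenomeUsageProfile",
    "filter_genes",
    "codon_counts",
    "gene_codon_frequencies",
    "genome_mean_usage",
    "select_heg",
    "gc_fraction",
    "genome_profile",
    "build_usage_matrix",
    "profiles_frame",
]

# codon -> column lookup for byte-level triplet indexing
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def filter_genes(
    cds: list[CDSFeature],
) -> tuple[list[CDSFeature], list[tuple[CDSFeature, str]]]:
    """Split CDS into kept genes and excluded (pseudogene / bad length) genes.

    Excluded reasons: ``"pseudo"`` for pseudogenes, ``"length"`` for a
    nucleotide count not divisible by 3. Pseudo takes precedence when both
    apply. kept + excluded partition the input.
    """
    kept: list[CDSFeature] = []
    excluded: list[tuple[CDSFeature, str]] = []
    for f in cds:
        if f.pseudo:
            excluded.append((f, "pseudo"))
        elif len(f.sequence) % 3 != 0:
            excluded.append((f, "length"))
        else:
            kept.append(f)
    return kept, excluded


def codon_counts(sequence: str) -> np.ndarray:
    """Integer counts of the 64 codons in a coding sequence.

    The sequence is scanned in consecutive, non-overlapping triplets from
    position 0. Triplets containing any non-ACGT letter are skipped (they
    enter neither numerator nor denominator).
    """
    if len(sequence) % 3 != 0:
        raise ValueError(
            f"coding sequence length {len(sequence)} not divisible by 3"
        )
    arr = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    triplets = arr.reshape(-1, 3)
    ok = (triplets >= 0).all(axis=1)
    idx = triplets[ok] @ np.array([16, 4, 1])
    return np.bincount(idx, minlength=64)


def gene_codon_frequencies(sequence: str) -> pd.Series:
    """Percentage of each of the 64 codons in one gene (sums to 100).

    Stop codons count like any other triplet; ambiguous triplets are dropped
    from both numerator and denominator.
    """
    counts = codon_counts(sequence)
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable codons (all triplets ambiguous)")
    return pd.Series(100.0 * counts / total, index=list(CODONS), name="usage")


def genome_mean_usage(vectors: list[pd.Series] | pd.DataFrame) -> pd.Series:
    """Unweighted per-codon mean of per-gene percentage vectors.

    Each gene contributes equally regardless of its length, so the result is
    the genome's average codon usage, not a codon-count-weighted pool.
    """
    if isinstance(vectors, pd.DataFrame):
        frame = vectors
    else:
        if len(vectors) == 0:
            raise ValueError("no genes: cannot average an empty set of vectors")
        frame = pd.DataFrame(vectors)
    if frame.empty:
        raise ValueError("no genes: cannot average an empty set of vectors")
    return frame.mean(axis=0)


@dataclass
class HEGCatalog:
    """Catalog of highly-expressed-gene classes and their matchers.

    A CDS matches a class when its gene symbol equals one of the accepted
    symbols (case-insensitive) or its product description contains one of the
    product substrings (case-insensitive).
    """

    classes: dict[str, tuple[tuple[str, ...], tuple[str, ...]]]

    def __post_init__(self) -> None:
        for name, (symbols, patterns) in self.classes.items():
            if not symbols and not patterns:
                raise ValueError(f"HEG class {name!r} has no matchers")

    def match(self, feature: CDSFeature) -> str | None:
        sym = feature.gene_symbol.lower()
        prod = feature.product.lower()
        for name, (symbols, patterns) in self.classes.items():
            if sym and sym in symbols:
                return name
            if prod and any(p in prod for p in patterns):
                return name
        return None


#: The 13 gene classes used as the highly-expressed proxy set: translation
#: elongation and initiation factors, selected ribosomal proteins, the two
#: large RNA-polymerase subunits and the major chaperones.
DEFAULT_HEG_CATALOG = HEGCatalog(
    {
        "EF-Tu": (("tuf", "tufa", "tufb"), ("elongation factor tu",)),
        "EF-G": (("fusa",), ("elongation factor g",)),
        "IF-1": (("infa",), ("translation initiation factor if-1",)),
        "IF-2": (("infb",), ("translation initiation factor if-2",)),
        "IF-3": (("infc",), ("translation initiation factor if-3",)),
        "L7/L12": (("rpll",), ("50s ribosomal protein l7/l12",)),
        "S1": (("rpsa",), ("30s ribosomal protein s1",)),
        "S6": (("rpsf",), ("30s ribosomal protein s6",)),
        "RpoA": (("rpoa",), ("rna polymerase subunit alpha",
                             "dna-directed rna polymerase subunit alpha")),
        "RpoB": (("rpob",), ("rna polymerase subunit beta",
                             "dna-directed rna polymerase subunit beta")),
        "DnaK": (("dnak",), ("chaperone protein dnak", "molecular chaperone dnak")),
        "GroEL": (("groel", "grol"), ("chaperonin groel", "60 kda chaperonin")),
        "ClpB": (("clpb",), ("chaperone protein clpb", "clpb protein")),
    }
)


def select_heg(
    cds: list[CDSFeature], catalog: HEGCatalog = DEFAULT_HEG_CATALOG
) -> tuple[list[CDSFeature], set[str], set[str]]:
    """Select the highly-expressed genes present in a genome.

    All CDS matching a class are returned (multi-copy genes, e.g. tufA and
    tufB, are all included). Missing classes are reported and the computation
    proceeds on whatever was found; zero matches raise.
    """
    heg: list[CDSFeature] = []
    found: set[str] = set()
    for f in cds:
        name = catalog.match(f)
        if name is not None:
            heg.append(f)
            found.add(name)
    if not found:
        raise ValueError("no HEG genes found")
    missing = set(catalog.classes) - found
    return heg, found, missing


def gc_fraction(assembly: GenomeAssembly | str) -> float:
    """G+C fraction over all genomic nucleotides, plasmids included.

    Computed as (G+C)/(A+C+G+T) on the concatenation of every replicon;
    ambiguity codes are excluded from numerator and denominator alike.
    """
    if isinstance(assembly, str):
        seqs = [assembly.upper()]
    else:
        if not assembly.replicons:
            raise ValueError(f"{assembly.genome_id}: no replicon sequences")
        seqs = [s for _, s in assembly.replicons]
    gc = at = 0
    for s in seqs:
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous nucleotides")
    return gc / (gc + at)


@dataclass
class GenomeUsageProfile:
    """One genome's usage vectors and summary metrics."""

    genome_id: str
    usage_all: pd.Series
    usage_heg: pd.Series | None
    n_genes_kept: int
    n_genes_excluded: int
    n_heg_found: int
    gc_fraction: float
    genome_size_bp: int
    n_cds: int
    heg_missing: set[str] = field(default_factory=set)


def genome_profile(
    assembly: GenomeAssembly,
    catalog: HEGCatalog = DEFAULT_HEG_CATALOG,
    exclude_stops: bool = False,
    weighted: bool = False,
    gc: float | None = None,
) -> GenomeUsageProfile:
    """Compute a genome's full usage profile from its assembly.

    Parameters
    ----------
    exclude_stops
        Drop the three stop triplets before normalizing each gene's vector.
        Off by default: percentages are over all codons of the coding
        sequence, stop included.
    weighted
        Average genes weighted by their codon counts (pooled tally) instead
        of the default unweighted per-gene mean. Provided for sensitivity
        analysis only.
    gc
        Genomic GC fraction, for inputs (CDS-only FASTA) where replicon
        sequences are unavailable. Computed from replicons when None.
    """
    kept, excluded = filter_genes(assembly.cds)
    if not kept:
        raise ValueError(f"{assembly.genome_id}: no usable genes after filtering")

    def _mean_usage(features: list[CDSFeature]) -> pd.Series:
        counts = np.stack([codon_counts(f.sequence) for f in features])
        if exclude_stops:
            from .codes import IS_STOP

            counts = counts * ~IS_STOP
        totals = counts.sum(axis=1)
        if (totals == 0).any():
            bad = [f.id for f, t in zip(features, totals) if t == 0]
            raise ValueError(f"no countable codons in genes {bad}")
        if weighted:
            vec = 100.0 * counts.sum(axis=0) / totals.sum()
        else:
            vec = (100.0 * counts / totals[:, None]).mean(axis=0)
        return pd.Series(vec, index=list(CODONS))

    usage_all = _mean_usage(kept)
    usage_heg: pd.Series | None = None
    n_found = 0
    missing: set[str] = set()
    try:
        heg, found, missing = select_heg(kept, catalog)
        usage_heg = _mean_usage(heg)
        n_found = len(found)
    except ValueError:
        log.warning("%s: no HEG genes found; usage_heg absent", assembly.genome_id)
        missing = set(catalog.classes)
    if missing and usage_heg is not None:
        log.info(
            "%s: %d HEG classes missing (%s); HEG usage from found genes",
            assembly.genome_id, len(missing), ", ".join(sorted(missing)),
        )
    return GenomeUsageProfile(
        genome_id=assembly.genome_id,
        usage_all=usage_all,
        usage_heg=usage_heg,
        n_genes_kept=len(kept),
        n_genes_excluded=len(excluded),
        n_heg_found=n_found,
        gc_fraction=gc_fraction(assembly) if gc is None else gc,
        genome_size_bp=assembly.genome_size_bp or sum(
            len(f.sequence) for f in assembly.cds
        ),
        n_cds=assembly.n_cds,
    )


def build_usage_matrix(
    profiles: list[GenomeUsageProfile], subset: str = "all"
) -> pd.DataFrame:
    """Assemble the genomes x 64-codons usage matrix.

    ``subset="heg"`` uses the highly-expressed-gene vectors; profiles lacking
    one are dropped with a logged warning. Row order follows input order.
    """
    if subset not in ("all", "heg"):
        raise ValueError(f"subset must be 'all' or 'heg', got {subset!r}")
    if not profiles:
        raise ValueError("no profiles")
    ids = [p.genome_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id in profiles")
    rows = {}
    for p in profiles:
        vec = p.usage_all if subset == "all" else p.usage_heg
        if vec is None:
            log.warning("%s: no HEG usage; dropped from HEG matrix", p.genome_id)
            continue
        rows[p.genome_id] = vec
    if not rows:
        raise ValueError("no rows to assemble")
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CODONS))


def profiles_frame(profiles: list[GenomeUsageProfile]) -> pd.DataFrame:
    """Per-genome summary table (one row per genome)."""
    return pd.DataFrame(
        {
            "n_genes_kept": [p.n_genes_kept for p in profiles],
            "n_genes_excluded": [p.n_genes_excluded for p in profiles],
            "n_heg_found": [p.n_heg_found for p in profiles],
            "gc_fraction": [p.gc_fraction for p in profiles],
            "genome_size_bp": [p.genome_size_bp for p in profiles],
            "n_cds": [p.n_cds for p in profiles],
        },
        index=pd.Index([p.genome_id for p in profiles], name="genome_id"),
    )
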