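"""Reading CDS inputs (FASTA dialect, GenBank flat files) and TSV result tables.

The CDS FASTA dialect follows RefSeq ``*_cds_from_genomic.fna`` conventions:
bracketed, order-free ``[key=value]`` tokens after the record id, of which
``gene``, ``product`` and ``pseudo`` are understood here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_BRACKET_TOKEN = re.compile(r"\[([^=\[\]]+)=([^\[\]]*)\]")


class ParseError(ValueError):
    """Raised for malformed input files."""


@dataclass
class CDSFeature:
    """One annotated protein-coding gene.

    ``sequence`` is the spliced coding sequence in reading direction,
    uppercased; non-ACGT letters are retained (the exclusion policy for
    ambiguous triplets belongs to codon counting, not I/O).
    """

    id: str
    sequence: str
    gene_symbol: str = ""
    product: str = ""
    pseudo: bool = False
    replicon_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"CDS {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()


@dataclass
class GenomeAssembly:
    """A genome: its replicons (chromosome plus any plasmids) and CDS set."""

    genome_id: str
    replicons: list[tuple[str, str]] = field(default_factory=list)
    cds: list[CDSFeature] = field(default_factory=list)

    @property
    def n_cds(self) -> int:
        """Number of non-pseudo CDS."""
        return sum(1 for f in self.cds if not f.pseudo)

    @property
    def genome_size_bp(self) -> int:
        return sum(len(s) for _, s in self.replicons)


def read_cds_fasta(path: str | Path) -> list[CDSFeature]:
    """Read a CDS FASTA file in the bracketed key=value header dialect.

    Header form: ``>id [gene=sym] [product=text] [pseudo=true|false]``; all
    bracketed tokens are optional and order-free. Missing keys default to
    empty strings / ``pseudo=False``. Sequences are uppercased. Duplicate ids
    raise :class:`ParseError`.
    """
    path = Path(path)
    features: list[CDSFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.readline()
        while first and not first.strip():
            first = fh.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}: line 1: FASTA must start with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(_BRACKET_TOKEN.findall(rec.description))
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate CDS id {rec.id!r}")
        seen.add(rec.id)
        features.append(
            CDSFeature(
                id=rec.id,
                sequence=str(rec.seq),
                gene_symbol=tokens.get("gene", ""),
                product=tokens.get("product", ""),
                pseudo=tokens.get("pseudo", "false").strip().lower()
                in ("true", "1", "yes"),
            )
        )
    return features


def read_genbank(path: str | Path, genome_id: str | None = None) -> GenomeAssembly:
    """Read a (possibly multi-record) GenBank flat file into a GenomeAssembly.

    Each record becomes a replicon; CDS features are extracted with their
    ``/gene``, ``/product`` and ``/pseudo`` qualifiers, and join/complement
    locations are spliced into a contiguous coding sequence in reading
    direction (Biopython ``feature.extract``). A CDS whose location exceeds
    the replicon length is skipped with a logged warning.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ParseError(f"{path}: no GenBank records found")
    asm = GenomeAssembly(genome_id=genome_id or records[0].id)
    counter = 0
    for rec in records:
        asm.replicons.append((rec.id, str(rec.seq).upper()))
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            counter += 1
            if int(feat.location.end) > len(rec.seq):
                log.warning(
                    "%s: CDS at %s exceeds replicon %s length %d; skipped",
                    path, feat.location, rec.id, len(rec.seq),
                )
                continue
            quals = feat.qualifiers
            fid = quals.get("locus_tag", quals.get("protein_id", [f"cds{counter}"]))[0]
            asm.cds.append(
                CDSFeature(
                    id=fid,
                    sequence=str(feat.extract(rec.seq)),
                    gene_symbol=quals.get("gene", [""])[0],
                    product=quals.get("product", [""])[0],
                    pseudo="pseudo" in quals,
                    replicon_id=rec.id,
                )
            )
    ids = [f.id for f in asm.cds]
    if len(set(ids)) != len(ids):
        # disambiguate duplicated locus tags rather than failing the genome
        seen: dict[str, int] = {}
        for f in asm.cds:
            n = seen.get(f.id, 0)
            seen[f.id] = n + 1
            if n:
                f.id = f"{f.id}_{n}"
    return asm


def write_matrix(rows: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Write a labeled numeric matrix as TSV, first column ``genome_id``.

    Row labels are genome ids; duplicate labels are an error. Values are
    written with >= 6 significant digits so a read/write round trip is exact
    on the decimal text.
    """
    if rows.index.has_duplicates:
        dups = rows.index[rows.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row labels: {dups}")
    out = rows.copy()
    out.index.name = "genome_id"
    out.to_csv(path, sep="\t", float_format=float_format)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col="genome_id", comment="#")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated genome_id rows: {dups}")
    return df


def read_presence_table(path: str | Path) -> pd.DataFrame:
    """Read a genome x marker presence/absence table (0/1 TSV) as booleans."""
    df = read_matrix(path)
    if not df.isin([0, 1, True, False]).all().all():
        raise ParseError(f"{path}: presence table must contain only 0/1 values")
    return df.astype(bool)
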