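"""tRNA gene inventories from tRNAscan-SE 2.0 output.

Genes are counted per anticodon with initiator tRNA-Met excluded (tRNAscan-SE
2.0 distinguishes initiator from elongator tRNA-Met), and the per-genome
counts are related to codon usage through either strict Watson-Crick pairing
(codon = reverse complement of the anticodon) or with the two classical
wobble rules at anticodon position 34 (G34 also reads the T-ending codon,
U34 also reads the G-ending codon). Correlation is Spearman's rank
coefficient across genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .codes import CODONS, revcomp
from .io import ParseError

__all__ = [
    "TRNAGene",
    "parse_trnascan",
    "count_anticodons",
    "anticodon_to_codon",
    "decoding_anticodons",
    "usage_vs_counts",
]

#: isotype labels marking the initiator tRNA-Met
INITIATOR_ISOTYPES = frozenset({"iMet", "fMet"})


@dataclass
class TRNAGene:
    genome_id: str
    isotype: str
    anticodon: str  # DNA alphabet, U already mapped to T; may be 'NNN'
    pseudo_flag: bool = False
    score: float | None = None


def parse_trnascan(path: str | Path, genome_id: str | None = None) -> list[TRNAGene]:
    """Parse tRNAscan-SE 2.0 tab-delimited output.

    Expects the 3-line header followed by data rows with at least 9 columns
    (sequence name, tRNA#, begin, end, isotype, anticodon, intron begin/end,
    score, and an optional trailing note column). ``pseudo`` in the note sets
    the pseudo flag; anticodons are normalized U->T.
    """
    path = Path(path)
    gid = genome_id or path.stem
    genes: list[TRNAGene] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        cols = [c.strip() for c in line.rstrip("\n").split("\t")]
        if len(cols) < 9:
            raise ParseError(
                f"{path}: row {lineno}: expected >= 9 tab-separated columns, "
                f"got {len(cols)}"
            )
        note = cols[9] if len(cols) > 9 else ""
        try:
            score = float(cols[8])
        except ValueError:
            score = None
        genes.append(
            TRNAGene(
                genome_id=gid,
                isotype=cols[4],
                anticodon=cols[5].upper().replace("U", "T"),
                pseudo_flag="pseudo" in note.lower(),
                score=score,
            )
        )
    return genes


def count_anticodons(
    genes: list[TRNAGene],
    exclude_initiator: bool = True,
    exclude_pseudo: bool = True,
) -> pd.DataFrame:
    """Gene counts per (genome, anticodon) as a genomes x anticodons frame.

    Initiator tRNA-Met rows (isotype iMet/fMet) and pseudo-tRNA rows are
    excluded by default; anticodons that could not be determined ('NNN' or
    non-triplet) are dropped.
    """
    counts: dict[str, dict[str, int]] = {}
    for g in genes:
        if exclude_initiator and g.isotype in INITIATOR_ISOTYPES:
            continue
        if exclude_pseudo and g.pseudo_flag:
            continue
        if len(g.anticodon) != 3 or any(b not in "ACGT" for b in g.anticodon):
            continue
        row = counts.setdefault(g.genome_id, {})
        row[g.anticodon] = row.get(g.anticodon, 0) + 1
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    df.index.name = "genome_id"
    return df.sort_index(axis=1)


def anticodon_to_codon(anticodon: str) -> str:
    """The perfectly (Watson-Crick) paired codon: the reverse complement."""
    if len(anticodon) != 3 or any(b not in "ACGT" for b in anticodon):
        raise ValueError(f"anticodon must be an ACGT triplet, got {anticodon!r}")
    return revcomp(anticodon)


def decoding_anticodons(codon: str, pairing: str = "perfect_only") -> list[str]:
    """Anticodons credited with decoding a codon under the pairing model.

    ``perfect_only``: the reverse complement. ``perfect_plus_wobble`` adds
    the classical position-34 rules: a codon ending in T is also read by the
    G34 anticodon (the one perfectly matching its C-ending synonym), and a
    codon ending in G by the corresponding U34 (T34 in DNA) anticodon.
    """
    perfect = revcomp(codon)
    if pairing == "perfect_only":
        return [perfect]
    if pairing != "perfect_plus_wobble":
        raise ValueError(f"unknown pairing mode {pairing!r}")
    anticodons = [perfect]
    prefix_rc = revcomp(codon[:2])  # anticodon positions 35,36
    if codon[2] == "T":
        anticodons.append("G" + prefix_rc)
    elif codon[2] == "G":
        anticodons.append("T" + prefix_rc)
    return anticodons


def usage_vs_counts(
    matrix: pd.DataFrame,
    counts: pd.DataFrame,
    pairing: str = "perfect_only",
) -> pd.DataFrame:
    """Spearman correlation of codon usage with decoding-tRNA gene count.

    For each codon, the usage column is correlated across genomes with the
    summed gene count of the anticodons credited under ``pairing``. Codons
    whose count vector has zero variance get an absent (NaN) correlation.
    """
    common = matrix.index.intersection(counts.index)
    if len(common) == 0:
        raise ValueError("no genomes shared between usage matrix and tRNA counts")
    usage = matrix.loc[common]
    cnt = counts.reindex(index=common, columns=None).fillna(0)
    rows = []
    for codon in usage.columns:
        acs = decoding_anticodons(codon, pairing)
        vec = np.zeros(len(common))
        for ac in acs:
            if ac in cnt.columns:
                vec += cnt[ac].to_numpy(dtype=float)
        if np.ptp(vec) == 0 or np.ptp(usage[codon].to_numpy()) == 0:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(usage[codon].to_numpy(), vec)
        rows.append(
            {
                "codon": codon,
                "anticodons": ",".join(acs),
                "n": len(common),
                "spearman_rho": rho,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("codon")
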