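"""Synthetic genome collections with known codon-usage structure.

The generator emulates a collection of bacterial genomes spanning a wide GC
range whose codon usage follows a family-constrained, GC-responsive model:

* amino-acid (synonymous-family) composition is held fixed across genomes,
  isolating codon *choice* from proteome composition;
* within each family, codon c has weight ``u0_c * exp(beta_c * (g - 0.5))``
  at mutational GC pressure ``g``, so ``beta_c`` is the codon's
  GC-responsiveness (0 = a low-variability codon) and the within-family
  shares follow a logistic curve in g;
* marker genes (standing in for tRNA-modification genes) multiply the
  weights of designated codons when present, and may themselves be drawn
  with a GC-dependent (logistic) presence probability;
* per-genome usage is perturbed by a Dirichlet draw (concentration
  ``noise_kappa`` x expected proportions) and genes are multinomial samples
  from it, so genome GC is an emergent property of the emitted codons.

Each genome is seeded from ``(seed, genome_index)`` so enlarging a
collection never reshuffles earlier genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import (
    CODONS,
    CODON_GC_COUNTS,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    gc_count,
)

__all__ = [
    "MarkerSpec",
    "SimulationConfig",
    "SimulatedCollection",
    "expected_usage",
    "expected_gc",
    "truth_slopes",
    "simulate_collection",
    "generate_collection",
    "emit_trnascan_fixture",
    "default_config",
    "recovery_config",
    "marker_power_config",
    "bimodal_mixture_usage",
]

#: Average bacterial proteome amino-acid composition (fractions, renormalized).
DEFAULT_AA_FREQUENCIES: dict[str, float] = {
    "A": 0.089, "R": 0.055, "N": 0.039, "D": 0.054, "C": 0.012,
    "Q": 0.039, "E": 0.062, "G": 0.078, "H": 0.021, "I": 0.060,
    "L": 0.100, "K": 0.064, "M": 0.022, "F": 0.041, "P": 0.044,
    "S": 0.061, "T": 0.054, "W": 0.012, "Y": 0.032, "V": 0.069,
}

#: Stop-codon weights (TAA-heavy, as in most bacteria).
DEFAULT_STOP_WEIGHTS: dict[str, float] = {"TAA": 0.6, "TAG": 0.1, "TGA": 0.3}

_SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


@dataclass
class MarkerSpec:
    """A marker gene: its presence rule and its codon-weight effect.

    ``presence`` is ``("bernoulli", p)`` or ``("logistic", a, b)`` giving
    presence probability ``1/(1+exp(-(a + b*g)))`` at GC pressure g.
    ``effect`` maps codons to within-family weight multipliers (> 0) applied
    when the marker is present.
    """

    name: str
    presence: tuple
    effect: dict[str, float] = field(default_factory=dict)

    def presence_probability(self, g: float) -> float:
        kind = self.presence[0]
        if kind == "bernoulli":
            return float(self.presence[1])
        if kind == "logistic":
            a, b = self.presence[1], self.presence[2]
            return float(1.0 / (1.0 + np.exp(-(a + b * g))))
        raise ValueError(f"unknown presence rule {kind!r}")

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.effect.values()):
            raise ValueError(f"marker {self.name}: multipliers must be > 0")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic genome collection."""

    n_genomes: int = 300
    genes_per_genome: int = 200
    gene_length_codons: int = 300  # sampled sense codons per gene (+ ATG + stop)
    gc_range: tuple[float, float] = (0.15, 0.75)
    family_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            aa: codons for aa, codons in SYNONYMOUS_FAMILIES.items() if aa != "*"
        }
    )
    aa_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_FREQUENCIES)
    )
    baseline_usage: dict[str, float] | None = None  # u0; None = uniform in family
    beta: dict[str, float] = field(default_factory=dict)
    stop_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STOP_WEIGHTS)
    )
    markers: list[MarkerSpec] = field(default_factory=list)
    noise_kappa: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        covered = sorted(c for fam in self.family_map.values() for c in fam)
        if covered != sorted(SENSE_CODONS):
            raise ValueError("family_map must partition the 61 sense codons")
        tot = sum(self.aa_frequencies.values())
        if not np.isclose(tot, 1.0, atol=1e-6):
            self.aa_frequencies = {k: v / tot for k, v in self.aa_frequencies.items()}
        if set(self.aa_frequencies) != set(self.family_map):
            raise ValueError("aa_frequencies keys must match family_map keys")
        if any(len(f) == 0 for f in self.family_map.values()):
            raise ValueError("infeasible config: empty synonymous family")

    # ---- array views (aligned with SENSE_CODONS) -------------------------

    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(family index, family aa-frequency, u0, beta) per sense codon."""
        fam_names = sorted(self.family_map)
        fam_of = np.empty(len(SENSE_CODONS), dtype=int)
        aa_freq = np.empty(len(fam_names))
        for fi, name in enumerate(fam_names):
            aa_freq[fi] = self.aa_frequencies[name]
            for c in self.family_map[name]:
                fam_of[_SENSE_INDEX[c]] = fi
        u0 = np.ones(len(SENSE_CODONS))
        if self.baseline_usage is not None:
            for c, w in self.baseline_usage.items():
                if c in _SENSE_INDEX:
                    u0[_SENSE_INDEX[c]] = w
        beta = np.zeros(len(SENSE_CODONS))
        for c, b in self.beta.items():
            if c in _SENSE_INDEX:
                beta[_SENSE_INDEX[c]] = b
        return fam_of, aa_freq, u0, beta

    def stop_distribution(self) -> np.ndarray:
        s = np.array([self.stop_weights.get(c, 0.0) for c in STOP_CODONS], float)
        if s.sum() <= 0:
            raise ValueError("stop weights must sum to a positive value")
        return s / s.sum()


def _sense_distribution(
    config: SimulationConfig, g: float, present_markers: set[str]
) -> np.ndarray:
    """Expected sense-codon proportions (sum 1) at GC pressure g."""
    fam_of, aa_freq, u0, beta = config._arrays()
    with np.errstate(over="ignore"):  # overflow is reported as the error below
        w = u0 * np.exp(beta * (g - 0.5))
    for m in config.markers:
        if m.name in present_markers:
            for c, mult in m.effect.items():
                if c in _SENSE_INDEX:
                    w[_SENSE_INDEX[c]] *= mult
    if not np.isfinite(w).all():
        raise ValueError("non-finite codon weights (beta too extreme?)")
    fam_sums = np.zeros(len(aa_freq))
    np.add.at(fam_sums, fam_of, w)
    return aa_freq[fam_of] * w / fam_sums[fam_of]


def expected_usage(
    config: SimulationConfig, g: float, present_markers: set[str] | None = None
) -> pd.Series:
    """Expected per-gene codon usage vector (%) at GC pressure ``g``.

    A gene is modeled as an ATG start, ``gene_length_codons`` sense codons
    drawn from the family model, and one stop codon from the stop-family
    weights (the stop family contributes exactly one codon per gene), so
    percentages are over ``gene_length_codons + 2`` codons.
    """
    lo, hi = config.gc_range
    if not lo <= g <= hi:
        raise ValueError(f"g={g} outside gc_range {config.gc_range}")
    q = _sense_distribution(config, g, present_markers or set())
    L = config.gene_length_codons
    usage = np.zeros(64)
    for c, qi in zip(SENSE_CODONS, q):
        usage[CODONS.index(c)] = L * qi
    usage[CODONS.index("ATG")] += 1.0
    for c, si in zip(STOP_CODONS, config.stop_distribution()):
        usage[CODONS.index(c)] += si
    usage *= 100.0 / (L + 2)
    return pd.Series(usage, index=list(CODONS))


def expected_gc(
    config: SimulationConfig, g: float, present_markers: set[str] | None = None
) -> float:
    """Expected GC fraction of the emitted coding sequences at pressure g."""
    usage = expected_usage(config, g, present_markers).to_numpy() / 100.0
    return float((usage * CODON_GC_COUNTS).sum() / 3.0)


def truth_slopes(config: SimulationConfig, n_grid: int = 201) -> pd.Series:
    """Expected usage-vs-GC regression slope per codon (markers absent).

    Computed by OLS of the noise-free expected usage curve against the
    expected realized GC fraction over a uniform grid of g spanning
    ``gc_range`` — the same scale the pipeline regresses on, since genome GC
    is emergent from codon composition.
    """
    gs = np.linspace(*config.gc_range, n_grid)
    x = np.array([expected_gc(config, g) for g in gs])
    y = np.stack([expected_usage(config, g).to_numpy() for g in gs])
    xc = x - x.mean()
    sxx = (xc**2).sum()
    if sxx < 1e-18:  # GC-flat model: every expected slope is zero
        return pd.Series(0.0, index=list(CODONS))
    slopes = xc @ (y - y.mean(axis=0)) / sxx
    return pd.Series(slopes, index=list(CODONS))


@dataclass
class SimulatedCollection:
    """In-memory synthetic collection plus the generating truth."""

    usage: pd.DataFrame        # genomes x 64 codons, per-genome mean usage (%)
    gc: pd.Series              # realized GC fraction per genome
    presence: pd.DataFrame     # genomes x markers booleans
    g_truth: pd.Series         # drawn GC pressure per genome
    beta: pd.Series            # per-codon responsiveness (0 for stops)
    expected_slopes: pd.Series # truth_slopes(config)
    config: SimulationConfig

    @property
    def profiles(self) -> pd.DataFrame:
        """Profile-style summary frame (gc_fraction, n_cds) for the pipeline."""
        return pd.DataFrame(
            {
                "gc_fraction": self.gc,
                "n_cds": self.config.genes_per_genome,
                "genome_size_bp": 3
                * (self.config.gene_length_codons + 2)
                * self.config.genes_per_genome,
            }
        )


def _draw_genome(
    config: SimulationConfig, index: int
) -> tuple[np.random.Generator, float, set[str], np.ndarray, np.ndarray]:
    """Per-genome RNG stream and the genome's latent state.

    Returns (rng, g, present markers, perturbed sense distribution,
    perturbed stop distribution).
    """
    rng = np.random.default_rng([config.seed, index])
    g = rng.uniform(*config.gc_range)
    present = {
        m.name for m in config.markers if rng.random() < m.presence_probability(g)
    }
    q = _sense_distribution(config, g, present)
    q = rng.dirichlet(np.maximum(config.noise_kappa * q, 1e-9))
    s = rng.dirichlet(np.maximum(config.noise_kappa * config.stop_distribution(), 1e-9))
    return rng, g, present, q, s


def simulate_collection(config: SimulationConfig) -> SimulatedCollection:
    """Draw a collection and return its usage matrix, GC and truth in memory.

    Per-gene multinomial draws of equal-length genes are pooled into one
    multinomial per genome: with equal gene lengths the unweighted mean of
    per-gene percentage vectors equals the pooled percentage vector exactly,
    so this is the distribution the file-emitting generator realizes, at a
    fraction of the cost.
    """
    n_sense = config.genes_per_genome * config.gene_length_codons
    usage = np.empty((config.n_genomes, 64))
    gcs = np.empty(config.n_genomes)
    g_truth = np.empty(config.n_genomes)
    pres_rows = []
    sense_cols = np.array([CODONS.index(c) for c in SENSE_CODONS])
    stop_cols = np.array([CODONS.index(c) for c in STOP_CODONS])
    atg = CODONS.index("ATG")
    for i in range(config.n_genomes):
        rng, g, present, q, s = _draw_genome(config, i)
        counts = np.zeros(64)
        counts[sense_cols] = rng.multinomial(n_sense, q)
        counts[stop_cols] += rng.multinomial(config.genes_per_genome, s)
        counts[atg] += config.genes_per_genome
        total = counts.sum()
        usage[i] = 100.0 * counts / total
        gcs[i] = (counts * CODON_GC_COUNTS).sum() / (3.0 * total)
        g_truth[i] = g
        pres_rows.append({m.name: (m.name in present) for m in config.markers})
    ids = pd.Index([f"sim{i:04d}" for i in range(config.n_genomes)], name="genome_id")
    beta = pd.Series(
        [config.beta.get(c, 0.0) for c in CODONS], index=list(CODONS)
    )
    return SimulatedCollection(
        usage=pd.DataFrame(usage, index=ids, columns=list(CODONS)),
        gc=pd.Series(gcs, index=ids, name="gc_fraction"),
        presence=pd.DataFrame(pres_rows, index=ids, dtype=bool)
        if config.markers
        else pd.DataFrame(index=ids),
        g_truth=pd.Series(g_truth, index=ids, name="g"),
        beta=beta,
        expected_slopes=truth_slopes(config),
        config=config,
    )


#: gene symbols written onto the first genes of every synthetic genome, so a
#: collection exercises the highly-expressed-subset selection end to end
HEG_GENE_SYMBOLS = (
    "tuf", "fusA", "infA", "infB", "infC", "rplL", "rpsA", "rpsF",
    "rpoA", "rpoB", "dnaK", "groEL", "clpB",
)


def generate_collection(config: SimulationConfig, out_dir) -> dict:
    """Write a synthetic collection to disk as per-genome CDS FASTA files.

    Emits ``<genome_id>.fna`` (one record per gene: ATG + sampled sense
    codons + one stop codon), ``presence.tsv`` and ``truth.tsv`` under
    ``out_dir``. The first 13 genes of each genome carry the
    highly-expressed-gene symbols (``[gene=...]`` header tokens) so the HEG
    selection path is exercised; their codon usage follows the same model as
    every other gene. Deterministic under a fixed seed: the same config
    writes byte-identical files. Returns paths and the truth tables.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sense = np.array(SENSE_CODONS)
    stops = np.array(STOP_CODONS)
    pres_rows, truth_rows, fasta_paths = [], [], []
    for i in range(config.n_genomes):
        rng, g, present, q, s = _draw_genome(config, i)
        gid = f"sim{i:04d}"
        path = out / f"{gid}.fna"
        with open(path, "w") as fh:
            for j in range(config.genes_per_genome):
                counts = rng.multinomial(config.gene_length_codons, q)
                body = np.repeat(sense, counts)
                rng.shuffle(body)
                stop = stops[rng.choice(3, p=s)]
                seq = "ATG" + "".join(body) + stop
                tag = (
                    f" [gene={HEG_GENE_SYMBOLS[j]}]"
                    if j < len(HEG_GENE_SYMBOLS)
                    else ""
                )
                fh.write(f">{gid}_g{j:04d}{tag}\n")
                for k in range(0, len(seq), 70):
                    fh.write(seq[k : k + 70] + "\n")
        fasta_paths.append(path)
        pres_rows.append(
            {"genome_id": gid, **{m.name: int(m.name in present) for m in config.markers}}
        )
        truth_rows.append({"genome_id": gid, "g": g})
    presence = pd.DataFrame(pres_rows).set_index("genome_id")
    truth = pd.DataFrame(truth_rows).set_index("genome_id")
    presence.to_csv(out / "presence.tsv", sep="\t")
    truth.to_csv(out / "truth.tsv", sep="\t", float_format="%.8g")
    return {
        "fasta": fasta_paths,
        "presence_path": out / "presence.tsv",
        "presence": presence,
        "truth": truth,
        "expected_slopes": truth_slopes(config),
    }


def emit_trnascan_fixture(
    usage: pd.DataFrame,
    out_dir,
    rule: str = "constant",
    scale: float = 2.0,
    seed: int = 0,
) -> list:
    """Write synthetic tRNAscan-SE 2.0 tabular files, one per genome.

    ``rule="constant"`` gives every anticodon one gene in every genome (a
    negative control: no usage/count relation). ``rule="usage_tied"`` sets
    each anticodon's gene count to a monotone function of the usage of its
    perfectly paired codon (a positive control for the correlation stage).
    An initiator tRNA-Met row is always included to exercise its exclusion.
    """
    from pathlib import Path

    from .codes import GENETIC_CODE, revcomp

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (
        "Sequence\t\ttRNA\tBounds\t\ttRNA\tAnti\tIntron Bounds\tInf\n"
        "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote\n"
        "--------\t------\t-----\t---\t----\t-----\t-----\t---\t-----\t----\n"
    )
    paths = []
    for gid in usage.index:
        path = out / f"{gid}.trnascan.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            num = 1
            for codon in usage.columns:
                aa = GENETIC_CODE[codon]
                if aa == "*":
                    continue
                anticodon = revcomp(codon)
                if rule == "constant":
                    n = 1
                elif rule == "usage_tied":
                    n = int(np.floor(usage.loc[gid, codon] * scale)) + 1
                else:
                    raise ValueError(f"unknown rule {rule!r}")
                for _ in range(n):
                    fh.write(
                        f"{gid}\t{num}\t{100 * num}\t{100 * num + 75}\t{aa}\t"
                        f"{anticodon}\t0\t0\t55.0\t\n"
                    )
                    num += 1
            # one initiator Met, excluded downstream by isotype
            fh.write(f"{gid}\t{num}\t99000\t99075\tiMet\tCAT\t0\t0\t60.0\t\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Named study designs
# ---------------------------------------------------------------------------


def _gc_tilted_beta(scale: float = 3.0) -> dict[str, float]:
    """beta_c = scale * (GC letters in c - family mean): GC-rich codons of
    every family respond positively to GC pressure."""
    beta = {}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        if aa == "*":
            continue
        mean_gc = float(np.mean([gc_count(c) for c in fam]))
        for c in fam:
            beta[c] = scale * (gc_count(c) - mean_gc)
    return beta


def default_config(
    n_genomes: int = 300,
    genes_per_genome: int = 200,
    seed: int = 0,
    beta_scale: float = 3.0,
) -> SimulationConfig:
    """The package's reference study conditions.

    A GC-responsive collection (every family GC-tilted with scale
    ``beta_scale``) carrying three markers that emulate the tRNA-modification
    gene structure: two markers whose presence probability rises with GC
    (recreating the low-GC-lacks-both stratification) of which one shifts
    Asp codon preference, and one GC-independent marker that doubles AAA
    weight and halves AAG (the s2U-pathway-like bimodality driver).
    """
    return SimulationConfig(
        n_genomes=n_genomes,
        genes_per_genome=genes_per_genome,
        beta=_gc_tilted_beta(beta_scale),
        markers=[
            MarkerSpec("tsaB_motif1", ("logistic", -8.0, 20.0)),
            MarkerSpec(
                "gluQRS_motif3", ("logistic", -6.0, 16.0),
                {"GAC": 1.5, "GAT": 1 / 1.5},
            ),
            MarkerSpec(
                "tusE_motif3", ("bernoulli", 0.5), {"AAA": 2.0, "AAG": 0.5}
            ),
        ],
        seed=seed,
    )


def recovery_config(
    n_genomes: int = 300, genes_per_genome: int = 100, seed: int = 0
) -> SimulationConfig:
    """Parameter-recovery design: strong responders next to flat codons.

    The five two-codon NNT/NNC families Asn, Asp, His, Phe and Tyr get
    beta = -3 / +3; Lys, Gln and Glu (NNA/NNG) are flat (beta = 0) matched
    controls; the remaining families carry the default GC tilt so genome GC
    spans a wide range. The eight matched families share one aa frequency
    (0.05) so flat and responsive codons have comparable baseline usage.
    noise_kappa 4000 puts per-codon noise near 0.3 percentage points.
    """
    beta = _gc_tilted_beta(3.0)
    for fam in ("N", "D", "H", "F", "Y"):
        for c in SYNONYMOUS_FAMILIES[fam]:
            beta[c] = 3.0 if c.endswith("C") else -3.0
    for fam in ("K", "Q", "E"):
        for c in SYNONYMOUS_FAMILIES[fam]:
            beta[c] = 0.0
    aa = dict(DEFAULT_AA_FREQUENCIES)
    for fam in ("N", "D", "H", "F", "Y", "K", "Q", "E"):
        aa[fam] = 0.05
    return SimulationConfig(
        n_genomes=n_genomes,
        genes_per_genome=genes_per_genome,
        aa_frequencies=aa,
        beta=beta,
        noise_kappa=4000.0,
        seed=seed,
    )


def marker_power_config(
    n_genomes: int = 200,
    genes_per_genome: int = 100,
    multiplier: float = 2.0,
    seed: int = 0,
) -> SimulationConfig:
    """Association power/size design: one Bernoulli(0.5) marker, AAA x2.

    All betas are zero so the marker effect is the only structure;
    ``multiplier=1.0`` gives the matching null design.
    """
    effect = {} if multiplier == 1.0 else {"AAA": multiplier}
    return SimulationConfig(
        n_genomes=n_genomes,
        genes_per_genome=genes_per_genome,
        beta={},
        markers=[MarkerSpec("tusE_motif3", ("bernoulli", 0.5), effect)],
        seed=seed,
    )


def bimodal_mixture_usage(
    n: int = 1000,
    seed: int = 0,
    means: tuple[float, float] = (0.3, 5.2),
    sds: tuple[float, float] = (0.15, 0.4),
) -> np.ndarray:
    """A 50/50 mixture of truncated-at-0 normals emulating bimodal AAA usage.

    Modes near 0-0.5% and 5-5.5%, the structure seen when a codon's usage is
    split by a marker that shifts it in half the collection.
    """
    rng = np.random.default_rng(seed)
    comp = rng.integers(0, 2, size=n)
    out = np.empty(n)
    for i, c in enumerate(comp):
        v = rng.normal(means[c], sds[c])
        while v < 0:  # truncation by redraw
            v = rng.normal(means[c], sds[c])
        out[i] = v
    return out
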