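"""End-to-end orchestration: usage -> variability -> GC fits -> association -> tRNA.

One call runs every stage in dependency order over a directory of CDS FASTA
files, GenBank files, or a freshly simulated collection, writing the standard
result tables (profiles.tsv, usage_all.tsv, usage_heg.tsv, variability.tsv,
slopes.tsv, assoc.tsv, gc4.tsv, trna_corr.tsv) plus a run log. Reruns on the
same inputs and config are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import association, gcfit, io, simulate, trna, usage, variability

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run."""

    mode: str = "simulated"  # cds-fasta | genbank | simulated
    input_dir: str | None = None
    presence_path: str | None = None
    trnascan_dir: str | None = None
    out_dir: str = "results"
    markers: list[str] = field(default_factory=list)
    t_low: float = 1.0
    t_high: float = 3.0
    alpha: float = association.ALPHA
    min_cds: int = 401
    min_group_size: int = 5
    exclude_stops: bool = False
    weighted: bool = False
    pairing: str = "perfect_only"
    four_group_a: str = "tsaB_motif1"
    four_group_b: str = "gluQRS_motif3"
    seed: int = 0
    sim_n_genomes: int = 60
    sim_genes_per_genome: int = 80

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.t_low < 0 or self.t_high < self.t_low:
            raise ValueError("thresholds must satisfy 0 <= t_low <= t_high")
        if self.mode not in ("cds-fasta", "genbank", "simulated"):
            raise ValueError(f"unknown input mode {self.mode!r}")


def _write(df: pd.DataFrame, path: Path, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "; ".join(f"{k}={v}" for k, v in params.items()) + "\n")
        df.to_csv(fh, sep="\t", float_format="%.6g")


def _load_profiles(config: PipelineConfig):
    """Stage 1: per-genome usage profiles from the configured input mode."""
    profiles = []
    if config.mode == "simulated":
        sim_cfg = simulate.SimulationConfig(
            n_genomes=config.sim_n_genomes,
            genes_per_genome=config.sim_genes_per_genome,
            beta=simulate._gc_tilted_beta(3.0),
            markers=simulate.default_config().markers,
            seed=config.seed,
        )
        gen_dir = Path(config.out_dir) / "genomes"
        generated = simulate.generate_collection(sim_cfg, gen_dir)
        fasta_paths = generated["fasta"]
        presence = generated["presence"].astype(bool)
        for path in fasta_paths:
            gid = path.stem
            cds = io.read_cds_fasta(path)
            asm = io.GenomeAssembly(
                genome_id=gid,
                replicons=[(gid, "".join(f.sequence for f in cds))],
                cds=cds,
            )
            profiles.append(
                usage.genome_profile(
                    asm, exclude_stops=config.exclude_stops, weighted=config.weighted
                )
            )
        return profiles, presence
    indir = Path(config.input_dir or "")
    if not indir.is_dir():
        raise FileNotFoundError(f"input directory not found: {indir}")
    pattern = "*.fna" if config.mode == "cds-fasta" else "*.gb*"
    paths = sorted(indir.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no {pattern} files under {indir}")
    for path in paths:
        if config.mode == "cds-fasta":
            cds = io.read_cds_fasta(path)
            asm = io.GenomeAssembly(
                genome_id=path.stem,
                replicons=[(path.stem, "".join(f.sequence for f in cds))],
                cds=cds,
            )
        else:
            asm = io.read_genbank(path, genome_id=path.stem)
        profiles.append(
            usage.genome_profile(
                asm, exclude_stops=config.exclude_stops, weighted=config.weighted
            )
        )
    presence = None
    if config.presence_path:
        presence = io.read_presence_table(config.presence_path)
    return profiles, presence


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the result tables under ``config.out_dir``.

    Returns a manifest mapping table names to paths. Missing inputs fail
    fast; stages whose inputs are unavailable (no presence table, no
    tRNAscan directory) are skipped with a logged notice.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log = out / "run_log.txt"
    handler = logging.FileHandler(run_log, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("codonvar")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict[str, Path] = {"run_log": run_log}
    # analysis parameters only: paths vary between runs without changing results
    _path_keys = {"input_dir", "presence_path", "trnascan_dir", "out_dir"}
    params = {
        k: v
        for k, v in asdict(config).items()
        if not k.startswith("sim_") and k not in _path_keys
    }
    try:
        profiles, presence = _load_profiles(config)
        log.info("profiles computed for %d genomes", len(profiles))
        prof_df = usage.profiles_frame(profiles)
        mat_all = usage.build_usage_matrix(profiles, "all")
        mat_heg_profiles = [p for p in profiles if p.usage_heg is not None]
        mat_heg = (
            usage.build_usage_matrix(mat_heg_profiles, "heg")
            if mat_heg_profiles
            else None
        )
        _write(prof_df, out / "profiles.tsv", params)
        _write(mat_all, out / "usage_all.tsv", params)
        manifest["profiles"] = out / "profiles.tsv"
        manifest["usage_all"] = out / "usage_all.tsv"
        if mat_heg is not None:
            _write(mat_heg, out / "usage_heg.tsv", params)
            manifest["usage_heg"] = out / "usage_heg.tsv"

        var_all = variability.variability_table(mat_all, (config.t_low, config.t_high))
        var_out = var_all
        if mat_heg is not None and len(mat_heg) >= 2:
            var_heg = variability.variability_table(
                mat_heg, (config.t_low, config.t_high)
            )
            folds = variability.sd_fold_changes(var_all, var_heg)
            var_out = var_all.join(folds[["sd_heg", "fold_change", "direction"]])
        _write(var_out, out / "variability.tsv", params)
        manifest["variability"] = out / "variability.tsv"

        fits = gcfit.fit_all_codons(mat_all, prof_df["gc_fraction"])
        rows, by_gc, by_third = gcfit.summarize_slopes(fits)
        _write(rows, out / "slopes.tsv", params)
        _write(by_gc, out / "slopes_by_gc_count.tsv", params)
        _write(by_third, out / "slopes_by_third_base.tsv", params)
        manifest["slopes"] = out / "slopes.tsv"

        if presence is not None and len(presence.columns):
            markers = config.markers or list(presence.columns)
            kept, removed = association.filter_small_genomes(prof_df, config.min_cds)
            if len(removed):
                log.info(
                    "small-genome filter: %d genomes with < %d CDS removed",
                    len(removed), config.min_cds,
                )
            resp = mat_heg if mat_heg is not None else mat_all
            resp = resp.loc[resp.index.intersection(kept.index)]
            assoc = association.compare_all(
                resp, presence, markers,
                alpha=config.alpha, min_group_size=config.min_group_size,
            )
            _write(assoc.set_index("marker"), out / "assoc.tsv", params)
            manifest["assoc"] = out / "assoc.tsv"
            if {config.four_group_a, config.four_group_b} <= set(presence.columns):
                g4 = association.four_group_gc(
                    kept["gc_fraction"], presence,
                    config.four_group_a, config.four_group_b, config.alpha,
                )
                g4_rows = g4.pairs.copy()
                g4_rows.insert(0, "kw_h", g4.kw_h)
                g4_rows.insert(1, "kw_p", g4.kw_p)
                _write(g4_rows.set_index("group_a"), out / "gc4.tsv", params)
                manifest["gc4"] = out / "gc4.tsv"
        else:
            log.info("no presence table: association stage skipped")

        if config.trnascan_dir:
            genes = []
            for path in sorted(Path(config.trnascan_dir).glob("*.t*sv")):
                genes.extend(trna.parse_trnascan(path, genome_id=path.stem.split(".")[0]))
            counts = trna.count_anticodons(genes)
            corr = trna.usage_vs_counts(mat_all, counts, config.pairing)
            _write(corr, out / "trna_corr.tsv", params)
            manifest["trna_corr"] = out / "trna_corr.tsv"

        with open(out / "run_metadata.json", "w") as fh:
            json.dump(
                {"config": asdict(config), "outputs": sorted(str(p) for p in manifest.values())},
                fh, indent=2, default=str,
            )
        manifest["run_metadata"] = out / "run_metadata.json"
    finally:
        root.removeHandler(handler)
        handler.close()
    return manifest
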