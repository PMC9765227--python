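"""Stage orchestration over a study bundle directory.

A bundle (as written by :func:`gtadapt.simulate.emit_study`, or assembled
from real data in the same layout) holds per-genome CDS FASTA and tRNA
inventories, a rooted Newick tree, the family table and the reference
family list.  Stages run in dependency order and each writes one TSV to
the output directory; a manifest records configuration, seed and per-stage
row counts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import enc as enc_mod
from . import screen as screen_mod
from .energetics import carbon_cost_cds, cost_vs_adaptation
from .groupstats import dunn_posthoc, kruskal_wallis
from .io import (
    FamilyTable,
    GenomeRecord,
    filter_short_genes,
    read_cds_fasta,
    read_newick,
    read_trna_pool,
)
from .tai import (
    DEFAULT_WOBBLE,
    WobbleWeights,
    absolute_adaptiveness,
    genome_tai,
    optimize_wobble,
    ptai,
    relative_adaptiveness,
)

logger = logging.getLogger(__name__)

STAGES = ("load", "enc", "tai", "ptai", "pgls_pairs", "screen", "cost", "stats")


@dataclass
class RunConfig:
    """Paths, thresholds and switches for a pipeline run."""

    bundle: Path
    outdir: Path
    alpha: float = 0.05
    reference_alpha: float = 0.001
    min_gene_length: int = 300
    min_genomes_all: int = 40
    min_genomes_cluster: int = 10
    optimize_s: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.bundle = Path(self.bundle)
        self.outdir = Path(self.outdir)
        if self.min_genomes_all <= 0 or self.min_genomes_cluster <= 0:
            raise ValueError("prevalence thresholds must be positive")


class PipelineState:
    """Data shared between stages of one run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.genomes: dict[str, GenomeRecord] = {}
        self.tree = None
        self.families: FamilyTable | None = None
        self.reference: list[str] = []
        self.counts: dict[str, pd.DataFrame] = {}
        self.enc_tables: dict[str, pd.DataFrame] = {}
        self.tai_tables: dict[str, pd.Series] = {}
        self.ptai_tables: dict[str, pd.Series] = {}
        self.matrix: pd.DataFrame | None = None
        self.manifest: dict = {"stages": {}, "config": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in vars(config).items()
        }}


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing input: {path}")
    return path


def stage_load(state: PipelineState) -> int:
    cfg = state.config
    tree_path = _require(cfg.bundle / "tree.nwk")
    fam_path = _require(cfg.bundle / "families.tsv")
    ref_path = _require(cfg.bundle / "reference_families.txt")
    state.tree = read_newick(tree_path)
    state.families = FamilyTable.from_tsv(fam_path)
    state.reference = [
        line.strip() for line in ref_path.read_text().splitlines() if line.strip()
    ]
    cds_dir = _require(cfg.bundle / "cds")
    trna_dir = _require(cfg.bundle / "trna")
    for fasta in sorted(cds_dir.glob("*.fasta")):
        genome_id = fasta.stem
        genome = read_cds_fasta(fasta, genome_id)
        genome = filter_short_genes(genome, cfg.min_gene_length)
        genome.trna_pool = read_trna_pool(_require(trna_dir / f"{genome_id}.tsv"))
        state.genomes[genome_id] = genome
        state.counts[genome_id] = enc_mod.codon_count_frame(genome.cds)
    if not state.genomes:
        raise FileNotFoundError(f"no CDS FASTA files under {cds_dir}")
    return len(state.genomes)


def stage_enc(state: PipelineState) -> int:
    frames = []
    for genome_id, genome in state.genomes.items():
        table = enc_mod.enc_table(genome.cds)
        state.enc_tables[genome_id] = table
        frames.append(table.assign(genome_id=genome_id))
    out = pd.concat(frames).reset_index()
    out.to_csv(state.config.outdir / "enc.tsv", sep="\t", index=False)
    return len(out)


def stage_tai(state: PipelineState) -> int:
    rows = 0
    frames = []
    for genome_id, genome in state.genomes.items():
        weights: WobbleWeights = DEFAULT_WOBBLE
        if state.config.optimize_s:
            proxy = state.enc_tables[genome_id]["deviation"].dropna()
            weights = optimize_wobble(
                state.counts[genome_id], genome.trna_pool, proxy
            ).weights
        w = relative_adaptiveness(
            absolute_adaptiveness(genome.trna_pool, weights)
        )
        tai = genome_tai(state.counts[genome_id], w)
        state.tai_tables[genome_id] = tai
        frames.append(tai.rename("tai").to_frame().assign(genome_id=genome_id))
        rows += len(tai)
    pd.concat(frames).reset_index().to_csv(
        state.config.outdir / "tai.tsv", sep="\t", index=False
    )
    return rows


def stage_ptai(state: PipelineState) -> int:
    frames = []
    for genome_id, tai in state.tai_tables.items():
        p = ptai(tai)
        state.ptai_tables[genome_id] = p
        frames.append(p.rename("ptai").to_frame().assign(genome_id=genome_id))
    out = pd.concat(frames).reset_index()
    out.to_csv(state.config.outdir / "ptai.tsv", sep="\t", index=False)
    state.matrix = screen_mod.build_ptai_matrix(state.families, state.ptai_tables)
    state.matrix.to_csv(state.config.outdir / "ptai_matrix.tsv", sep="\t")
    return len(out)


def stage_pgls_pairs(state: PipelineState) -> int:
    table = screen_mod.reference_pairwise(
        state.matrix, state.reference, state.tree,
        alpha=state.config.reference_alpha,
    )
    table.to_csv(state.config.outdir / "reference_pairs.tsv", sep="\t", index=False)
    flagged = screen_mod.flag_discordant_reference(
        table, alpha=state.config.reference_alpha
    )
    if flagged:
        logger.warning("reference families with discordant trends: %s", flagged)
    return len(table)


def stage_screen(state: PipelineState) -> int:
    candidates = [
        f for f in state.matrix.columns if f not in set(state.reference)
    ]
    report = screen_mod.screen_families(
        state.matrix, candidates, state.reference, state.tree,
        alpha=state.config.alpha,
    )
    report.to_csv(state.config.outdir / "screen.tsv", sep="\t")
    return len(report)


def stage_cost(state: PipelineState) -> int:
    rows = []
    for genome_id, genome in state.genomes.items():
        ptais = state.ptai_tables[genome_id]
        for gene_id, seq in genome.cds.items():
            cost = carbon_cost_cds(seq, gene_id=gene_id)
            rows.append((genome_id, gene_id, cost.total, cost.per_residue,
                         ptais.get(gene_id, math.nan)))
    out = pd.DataFrame(
        rows, columns=["genome_id", "gene_id", "total_carbons", "per_residue",
                       "ptai"]
    )
    out.to_csv(state.config.outdir / "carbon_cost.tsv", sep="\t", index=False)
    corr = cost_vs_adaptation(
        pd.Series(out["per_residue"].to_numpy()),
        pd.Series(out["ptai"].to_numpy()),
    )
    pd.DataFrame([vars(corr)]).to_csv(
        state.config.outdir / "cost_correlation.tsv", sep="\t", index=False
    )
    return len(out)


def stage_stats(state: PipelineState) -> int:
    """Group comparison of ptAI across the reference families."""
    groups, labels = [], []
    for fam in state.reference:
        values = state.matrix[fam].dropna().to_numpy()
        if len(values):
            groups.append(values)
            labels.append(fam)
    kw = kruskal_wallis(groups)
    dunn = dunn_posthoc(groups, labels)
    pd.DataFrame([vars(kw)]).to_csv(
        state.config.outdir / "kruskal_wallis.tsv", sep="\t", index=False
    )
    dunn.to_csv(state.config.outdir / "dunn.tsv", sep="\t", index=False)
    return len(dunn)


_STAGE_FUNCS = {
    "load": stage_load,
    "enc": stage_enc,
    "tai": stage_tai,
    "ptai": stage_ptai,
    "pgls_pairs": stage_pgls_pairs,
    "screen": stage_screen,
    "cost": stage_cost,
    "stats": stage_stats,
}

_DEPS = {
    "enc": ("load",),
    "tai": ("load", "enc"),
    "ptai": ("load", "enc", "tai"),
    "pgls_pairs": ("load", "enc", "tai", "ptai"),
    "screen": ("load", "enc", "tai", "ptai"),
    "cost": ("load", "enc", "tai", "ptai"),
    "stats": ("load", "enc", "tai", "ptai"),
}


def run(stages: list[str], config: RunConfig) -> PipelineState:
    """Run the requested stages (with their dependencies) in order."""
    wanted: list[str] = []
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        for dep in _DEPS.get(stage, ()) + (stage,):
            if dep not in wanted:
                wanted.append(dep)
    wanted.sort(key=STAGES.index)
    config.outdir.mkdir(parents=True, exist_ok=True)
    state = PipelineState(config)
    for stage in wanted:
        try:
            n_rows = _STAGE_FUNCS[stage](state)
        except Exception:
            _write_manifest(state, partial=True)
            raise
        state.manifest["stages"][stage] = {"rows": int(n_rows)}
        logger.info("stage %s: %d rows", stage, n_rows)
    _write_manifest(state)
    return state


def run_all(config: RunConfig) -> PipelineState:
    return run(list(STAGES), config)


def _write_manifest(state: PipelineState, partial: bool = False) -> None:
    from . import __version__

    state.manifest["version"] = __version__
    name = "manifest.json.partial" if partial else "manifest.json"
    (state.config.outdir / name).write_text(
        json.dumps(state.manifest, indent=2, sort_keys=True) + "\n"
    )
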