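"""Self-contained synthetic studies: a Yule tree over genomes, per-genome
tRNA pools, gene families (reference, planted and null, with paralogs) and
coding sequences whose codon usage encodes a latent, tree-structured
adaptation trait.

The generator emulates the statistical structure of a comparative
codon-usage study: a shared "activity" trait evolves by Brownian motion on
the tree; reference and planted families track that trait (plus family
noise) while null families follow independent Brownian traits.  The trait
is mapped through a logistic link to a per-gene selection strength
``s_gene`` in [0, 1]; each codon of a gene is then drawn either from the
tRNA-adapted distribution (probability ``s_gene``) or from a GC-driven
background.  Everything is reproducible from one master seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .codes import AA_TO_CODONS, CODON_INDEX, CODON_TO_AA, SENSE_CODONS, revcomp
from .energetics import SIDE_CHAIN_CARBON
from .io import FamilyTable, GenomeRecord, TrnaPool, write_cds_fasta
from .pgls import tree_structure
from .tai import DEFAULT_WOBBLE, WobbleWeights, absolute_adaptiveness, relative_adaptiveness

# roughly bacterial average amino-acid composition (relative weights)
AA_COMPOSITION: dict[str, float] = {
    "A": 9.0, "R": 5.5, "N": 4.0, "D": 5.2, "C": 1.0,
    "Q": 4.0, "E": 6.0, "G": 7.5, "H": 2.0, "I": 6.0,
    "L": 10.0, "K": 5.0, "M": 2.5, "F": 4.0, "P": 4.5,
    "S": 6.0, "T": 5.5, "W": 1.2, "Y": 3.0, "V": 7.0,
}


@dataclass
class SimConfig:
    """Study-generating parameters.

    Defaults describe the standard synthetic study: 60 genomes, a
    12-family reference set, 10 planted co-adapted families and 200 null
    families, gene lengths of 150-350 codons, tree depth ~1 with Brownian
    trait variance 1 and family-level noise sd 0.3.
    """

    n_genomes: int = 60
    birth_rate: float = 1.0
    n_reference: int = 12
    n_planted: int = 10
    n_null: int = 200
    reference_prevalence: float = 1.0
    planted_prevalence: float = 0.95
    null_prevalence_range: tuple[float, float] = (0.55, 1.0)
    paralog_prob: float = 0.1
    brownian_sigma2: float = 1.0
    shared_white_sd: float = 0.6
    family_noise_sd: float = 0.1
    link_scale: float = 2.0
    beta_sel: float = 1.0
    gc_target: float = 0.55
    length_range: tuple[int, int] = (250, 500)  # codons
    trna_base_scale: float = 1.0
    cost_coupling: bool = False
    cost_coupling_strength: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 4:
            raise ValueError("need at least 4 genomes")
        if not 0.0 <= self.beta_sel <= 1.0:
            raise ValueError("beta_sel must be in [0, 1]")
        if self.birth_rate <= 0:
            raise ValueError("birth rate must be positive")


@dataclass
class Study:
    """An in-memory synthetic study bundle."""

    config: SimConfig
    tree: dendropy.Tree
    genomes: dict[str, GenomeRecord]
    families: FamilyTable
    reference: list[str]
    ground_truth: pd.DataFrame  # per (family, genome): kind, trait, s_gene


# ---------------------------------------------------------------------------
# Tree and traits


def simulate_tree(n_genomes: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Seeded Yule tree with ``n_genomes`` tips, rescaled to mean
    root-to-tip depth 1; tips relabeled G001..; tiny branches floored so
    the Brownian covariance stays comfortably non-singular."""
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_genomes, rng=rng
    )
    tree.seed_node.edge.length = None  # the stem is not part of the study
    # the simulator stops exactly at the n-th birth, leaving the youngest
    # tips with zero-length branches; extend every leaf by the waiting time
    # to the next speciation so the tree stays ultrametric and nonsingular
    extra = rng.expovariate(n_genomes * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 1e-6:
            edge.length = 1e-6
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    scale = float(np.mean(depths))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= scale
    for i, leaf in enumerate(
        sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label), 1
    ):
        leaf.taxon.label = f"G{i:03d}"
    tree.is_rooted = True
    return tree


def _brownian_sample(chol: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return chol @ rng.standard_normal(chol.shape[0])


def simulate_latent_traits(
    tree: dendropy.Tree, config: SimConfig, rng: np.random.Generator
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Latent adaptation traits for every family in every genome.

    Returns ``(shared_trait, family_traits, s_gene)``.  The shared
    "activity" trait is a Brownian realization on the tree plus a
    genome-specific white component (``shared_white_sd``): activity is
    heritable but also reflects each genome's own ecology.  The white
    component is what makes co-adaptation identifiable to PGLS — were the
    shared trait a pure Brownian path, "family y tracks family x" and
    "family y is independent Brownian motion on the same tree" would be
    nearly indistinguishable.  Reference and planted family traits are the
    shared trait plus i.i.d. noise; null traits are independent Brownian
    realizations (plus their own white component); s_gene maps each trait
    through the logistic link scaled by ``beta_sel``.
    """
    structure = tree_structure(tree)
    labels = list(structure.labels)
    C = config.brownian_sigma2 * structure.covariance()
    chol = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))
    white = config.shared_white_sd
    shared = pd.Series(
        _brownian_sample(chol, rng) + rng.normal(0.0, white, size=len(labels)),
        index=labels, name="shared",
    )

    names = family_names(config)
    traits = {}
    for fam in names["reference"] + names["planted"]:
        noise = rng.normal(0.0, config.family_noise_sd, size=len(labels))
        traits[fam] = shared.to_numpy() + noise
    for fam in names["null"]:
        traits[fam] = _brownian_sample(chol, rng) + rng.normal(
            0.0, white, size=len(labels)
        )
    family_traits = pd.DataFrame(traits, index=labels)
    s_gene = config.beta_sel / (1.0 + np.exp(-config.link_scale * family_traits))
    return shared, family_traits, s_gene


def family_names(config: SimConfig) -> dict[str, list[str]]:
    return {
        "reference": [f"REF{i:02d}" for i in range(1, config.n_reference + 1)],
        "planted": [f"PLT{i:02d}" for i in range(1, config.n_planted + 1)],
        "null": [f"NUL{i:03d}" for i in range(1, config.n_null + 1)],
    }


# ---------------------------------------------------------------------------
# tRNA pools


def trna_template() -> dict[str, int]:
    """A bacteria-like anticodon inventory covering every codon box.

    Real bacterial tRNA sets are skewed: every box keeps a high-copy
    G-wobble anticodon (reads ..C directly and ..U through G:U pairing),
    but only about half the boxes carry the U-wobble anticodon that reads
    ..A/..G codons; the rest offer a single C-wobble copy, leaving their
    A-ending codons nearly unreadable.  That skew is what makes codon
    choice informative about adaptation to the pool.  Met and Ile2 share
    the CAT anticodon (isotype labels are not emitted, so downstream
    analysis exercises the shared-count path).
    """
    template: dict[str, int] = {}
    for c1 in "TCAG":
        for c2 in "TCAG":
            box_sense = [c1 + c2 + c3 for c3 in "TCAG" if c1 + c2 + c3 in CODON_TO_AA]
            if not box_sense:
                continue
            rich = c1 in "AG"  # half the boxes get the U-wobble reader
            picks = [("G", "C", 6)]
            if rich:
                picks.append(("T", "A", 2))
            else:
                picks.append(("C", "G", 1))
            for wobble, codon3, copies in picks:
                codon = c1 + c2 + codon3
                if codon not in CODON_TO_AA:
                    continue  # stop codon
                anticodon = wobble + revcomp(c1 + c2)
                template[anticodon] = copies
    template["CAT"] = 3  # elongator Met + lysidine Ile2
    return template


def simulate_trna_pool(rng: np.random.Generator, scale: float = 1.0) -> TrnaPool:
    """Per-genome pool: Poisson noise around the template (zeros kept, so
    some codons rely on wobble decoding or on the zero-replacement rule)."""
    counts = {}
    for anticodon, copies in trna_template().items():
        n = int(rng.poisson(copies * scale))
        if n > 0:
            counts[anticodon] = n
    counts.setdefault("CAT", 1)  # a genome cannot lack initiator/elongator Met
    return TrnaPool(counts=counts)


# ---------------------------------------------------------------------------
# Coding sequences


def _background_codon_weights(gc: float) -> np.ndarray:
    """Mutation-driven codon weights: independent positions with
    P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2."""
    p = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    return np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in SENSE_CODONS])


def _aa_weights(s_gene: float, config: SimConfig) -> np.ndarray:
    aas = sorted(AA_COMPOSITION)
    w = np.array([AA_COMPOSITION[a] for a in aas], dtype=float)
    if config.cost_coupling:
        cost = np.array([SIDE_CHAIN_CARBON[a] for a in aas], dtype=float)
        w = w * np.exp(-config.cost_coupling_strength * s_gene * (cost - cost.mean()) / 4.0)
    return w / w.sum()


def simulate_cds(
    s_gene: float,
    length: int,
    pool: TrnaPool,
    gc: float,
    rng: np.random.Generator,
    config: SimConfig | None = None,
    wobble: WobbleWeights = DEFAULT_WOBBLE,
    w: np.ndarray | None = None,
) -> str:
    """One CDS of ``length`` codons (plus ATG start and TAA stop).

    Each codon is drawn, within its amino acid's synonymous family, from a
    mixture: with probability ``s_gene`` proportionally to the pool's
    relative adaptiveness w (raw, so codons with no decoding tRNA are
    never chosen by the adapted component; an amino acid with no decodable
    codon at all falls back to the background), otherwise proportionally
    to the GC-driven background.  ``w`` may be passed in (raw scale) to
    amortize the per-pool adaptiveness computation.
    """
    if length < 100:
        raise ValueError("gene body must be at least 100 codons")
    if w is None:
        w = relative_adaptiveness(
            absolute_adaptiveness(pool, wobble), replace_zeros=False
        )
    background = _background_codon_weights(gc)
    config = config or SimConfig()
    aas = sorted(AA_COMPOSITION)
    aa_seq = rng.choice(len(aas), size=length, p=_aa_weights(s_gene, config))
    adapted = rng.random(length) < s_gene
    # draw codons per (amino acid, mixture component) block; positions within
    # a block are exchangeable, so block-wise sampling is equivalent to the
    # per-position mixture and far cheaper
    codons = np.empty(length, dtype=object)
    for k, aa in enumerate(aas):
        syn = AA_TO_CODONS[aa]
        idx = [CODON_INDEX[c] for c in syn]
        for weights, mask in ((w, (aa_seq == k) & adapted),
                              (background, (aa_seq == k) & ~adapted)):
            n_here = int(mask.sum())
            if n_here == 0:
                continue
            block = weights[idx]
            if block.sum() <= 0:  # no decodable codon: background fallback
                block = background[idx]
            probs = block / block.sum()
            picks = rng.choice(len(syn), size=n_here, p=probs)
            codons[mask] = [syn[p] for p in picks]
    return "ATG" + "".join(codons.tolist()) + "TAA"


# ---------------------------------------------------------------------------
# Whole-study assembly


def simulate_study(config: SimConfig) -> Study:
    """Generate the full in-memory bundle from the master seed.

    Per-component RNG streams are spawned deterministically from the
    master seed so stages are individually reproducible.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    tree = simulate_tree(config.n_genomes, config.birth_rate,
                         seed=int(seeds[0].generate_state(1)[0] % (2**31)))
    rng_traits = np.random.default_rng(seeds[1])
    rng_pools = np.random.default_rng(seeds[2])
    rng_seq = np.random.default_rng(seeds[3])

    shared, traits, s_gene = simulate_latent_traits(tree, config, rng_traits)
    genome_ids = list(traits.index)
    names = family_names(config)

    pools = {g: simulate_trna_pool(rng_pools, config.trna_base_scale)
             for g in genome_ids}
    w_by_genome = {
        g: relative_adaptiveness(
            absolute_adaptiveness(pools[g], DEFAULT_WOBBLE), replace_zeros=False
        )
        for g in genome_ids
    }

    # presence/absence per family
    prevalence: dict[str, float] = {}
    for fam in names["reference"]:
        prevalence[fam] = config.reference_prevalence
    for fam in names["planted"]:
        prevalence[fam] = config.planted_prevalence
    lo, hi = config.null_prevalence_range
    for fam in names["null"]:
        prevalence[fam] = float(rng_traits.uniform(lo, hi))

    rows = []
    truth_rows = []
    genomes: dict[str, GenomeRecord] = {}
    all_families = names["reference"] + names["planted"] + names["null"]
    kind_of = {f: k for k, fams in names.items() for f in fams}
    lo_len, hi_len = config.length_range
    for g in genome_ids:
        cds: dict[str, str] = {}
        for fam in all_families:
            if rng_seq.random() >= prevalence[fam]:
                continue
            n_copies = 1
            if rng_seq.random() < config.paralog_prob:
                n_copies = 2
            s = float(s_gene.loc[g, fam])
            for copy in range(1, n_copies + 1):
                gene_id = f"{g}_{fam}_{copy}"
                length = int(rng_seq.integers(lo_len, hi_len + 1))
                cds[gene_id] = simulate_cds(
                    s, length, pools[g], config.gc_target, rng_seq,
                    config=config, w=w_by_genome[g],
                )
                rows.append((g, fam, gene_id))
            truth_rows.append(
                (fam, g, kind_of[fam], float(traits.loc[g, fam]), s, n_copies)
            )
        genomes[g] = GenomeRecord(genome_id=g, cds=cds, trna_pool=pools[g])

    families = FamilyTable(
        frame=pd.DataFrame(rows, columns=["genome_id", "family_id", "gene_id"])
    )
    ground_truth = pd.DataFrame(
        truth_rows,
        columns=["family_id", "genome_id", "kind", "trait", "s_gene", "n_copies"],
    )
    return Study(config, tree, genomes, families, names["reference"], ground_truth)


def emit_study(config: SimConfig, outdir: str | Path) -> Path:
    """Write a study bundle to disk in the package's input formats.

    Layout: ``tree.nwk``, ``families.tsv``, ``reference_families.txt``,
    ``ground_truth.tsv``, ``config.json`` and per-genome
    ``cds/<genome>.fasta`` + ``trna/<genome>.tsv``.
    """
    outdir = Path(outdir)
    study = simulate_study(config)
    (outdir / "cds").mkdir(parents=True, exist_ok=True)
    (outdir / "trna").mkdir(parents=True, exist_ok=True)
    study.tree.write(path=str(outdir / "tree.nwk"), schema="newick",
                     suppress_rooting=True)
    study.families.to_tsv(outdir / "families.tsv")
    (outdir / "reference_families.txt").write_text(
        "\n".join(study.reference) + "\n"
    )
    study.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=2) + "\n")
    for g, genome in study.genomes.items():
        write_cds_fasta(genome, outdir / "cds" / f"{g}.fasta")
        genome.trna_pool.to_tsv(outdir / "trna" / f"{g}.tsv")
    return outdir
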