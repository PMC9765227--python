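"""Readers and writers for the external formats and the per-genome data model.

Supported inputs: per-genome CDS FASTA, tRNA inventories (either the
tRNAscan-SE v2 "final results" table or a plain two-column
``anticodon<TAB>count`` TSV), a rooted Newick phylogeny with branch
lengths, and the gene-family membership TSV
(``genome_id<TAB>family_id<TAB>gene_id``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_SEQ = re.compile(r"^[ACGTN]*$")
_VALID_ANTICODON = re.compile(r"^[ACGT]{3}$")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed or fails validation."""


# ---------------------------------------------------------------------------
# tRNA pools


@dataclass
class TrnaPool:
    """tRNA gene copy numbers per anticodon (tGCN), the abundance proxy.

    ``isotypes`` optionally resolves one anticodon into per-isotype copy
    numbers (needed to split the CAT anticodon between elongator Met and
    the lysidine-modified Ile2 tRNA); when absent the total count is used
    for every role of that anticodon.
    """

    counts: dict[str, int] = field(default_factory=dict)
    isotypes: dict[str, dict[str, int]] | None = None

    def __post_init__(self) -> None:
        for anticodon, n in self.counts.items():
            if not _VALID_ANTICODON.match(anticodon):
                raise FormatError(f"invalid anticodon {anticodon!r}")
            if n < 0:
                raise FormatError(f"negative copy number for {anticodon}")

    def count(self, anticodon: str) -> int:
        return self.counts.get(anticodon, 0)

    def isotype_count(self, anticodon: str, isotype_prefix: str) -> int | None:
        """Copies of ``anticodon`` whose isotype starts with ``isotype_prefix``.

        Returns None when no isotype labels are available.
        """
        if self.isotypes is None or anticodon not in self.isotypes:
            return None
        return sum(
            n
            for iso, n in self.isotypes[anticodon].items()
            if iso.startswith(isotype_prefix)
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TrnaPool":
        """Read a plain ``anticodon<TAB>count`` TSV (header optional)."""
        counts: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.lower().startswith("anticodon"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(f"{path}: line {lineno}: expected 2 columns")
                anticodon, raw = parts[0].upper(), parts[1]
                try:
                    n = int(raw)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: bad count {raw!r}"
                    ) from exc
                counts[anticodon] = counts.get(anticodon, 0) + n
        return cls(counts=counts)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("anticodon\tcount\n")
            for anticodon in sorted(self.counts):
                fh.write(f"{anticodon}\t{self.counts[anticodon]}\n")


def read_trnascan_table(path: str | Path) -> TrnaPool:
    """Parse tRNAscan-SE v2 tabular output into a :class:`TrnaPool`.

    Copy number per anticodon is the number of rows carrying it.  Rows whose
    note column contains "pseudo" are excluded (pseudogenes do not contribute
    to the functional tRNA pool) and rows with an undetermined anticodon
    (containing N) are skipped with a warning.
    """
    counts: dict[str, int] = {}
    isotypes: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("Sequence", "Name", "----")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise FormatError(
                    f"{path}: row {lineno}: expected >=6 tab-separated columns"
                )
            isotype = parts[4].strip()
            anticodon = parts[5].strip().upper().replace("U", "T")
            note = parts[9].strip().lower() if len(parts) > 9 else ""
            if "pseudo" in note or "pseudo" in isotype.lower():
                continue
            if "N" in anticodon or not _VALID_ANTICODON.match(anticodon):
                logger.warning(
                    "%s: row %d: undetermined anticodon %r skipped",
                    path, lineno, anticodon,
                )
                continue
            counts[anticodon] = counts.get(anticodon, 0) + 1
            iso_map = isotypes.setdefault(anticodon, {})
            iso_map[isotype] = iso_map.get(isotype, 0) + 1
    return TrnaPool(counts=counts, isotypes=isotypes)


def read_trna_pool(path: str | Path) -> TrnaPool:
    """Read a tRNA inventory, auto-detecting the dialect.

    Files whose first data row has >=6 columns are treated as tRNAscan-SE
    output, otherwise as a two-column ``anticodon<TAB>count`` TSV.
    """
    with open(path) as fh:
        for line in fh:
            if line.strip():
                ncols = len(line.rstrip("\n").split("\t"))
                break
        else:
            ncols = 2
    if ncols >= 6 or Path(path).name.lower().endswith((".trnascan", ".ss.txt")):
        return read_trnascan_table(path)
    return TrnaPool.from_tsv(path)


# ---------------------------------------------------------------------------
# Genomes


@dataclass
class GenomeRecord:
    """One genome: its label, coding sequences and (optionally) tRNA pool."""

    genome_id: str
    cds: dict[str, str] = field(default_factory=dict)
    trna_pool: TrnaPool | None = None

    def __post_init__(self) -> None:
        for gene_id, seq in self.cds.items():
            if not _VALID_SEQ.match(seq):
                raise FormatError(
                    f"{self.genome_id}/{gene_id}: sequence contains characters "
                    "outside A/C/G/T/N"
                )


def read_cds_fasta(path: str | Path, genome_id: str) -> GenomeRecord:
    """Read coding-strand CDS sequences from a FASTA file.

    Record ids become gene ids; sequences are upper-cased.  Duplicate gene
    ids and malformed records raise :class:`FormatError`.
    """
    cds: dict[str, str] = {}
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in cds:
                raise FormatError(f"{path}: duplicate gene id {record.id!r}")
            cds[record.id] = str(record.seq).upper()
    except FormatError:
        raise
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FASTA: {exc}") from exc
    if not cds:
        logger.warning("%s: no sequences found", path)
    return GenomeRecord(genome_id=genome_id, cds=cds)


def write_cds_fasta(genome: GenomeRecord, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(genome.cds):
            fh.write(f">{gene_id}\n")
            seq = genome.cds[gene_id]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def filter_short_genes(genome: GenomeRecord, min_len: int = 300) -> GenomeRecord:
    """Drop genes shorter than ``min_len`` nucleotides (default 300).

    Short genes are removed because their codon-usage statistics are
    dominated by sampling noise.  Idempotent; returns a new record.
    """
    kept = {g: s for g, s in genome.cds.items() if len(s) >= min_len}
    removed = len(genome.cds) - len(kept)
    if removed:
        logger.info("%s: removed %d genes shorter than %d nt",
                    genome.genome_id, removed, min_len)
    if not kept and genome.cds:
        logger.warning("%s: all genes shorter than %d nt", genome.genome_id, min_len)
    return replace(genome, cds=kept)


# ---------------------------------------------------------------------------
# Gene families


@dataclass
class FamilyTable:
    """Gene-family membership: rows of (genome_id, family_id, gene_id)."""

    frame: pd.DataFrame  # columns: genome_id, family_id, gene_id

    COLUMNS = ("genome_id", "family_id", "gene_id")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise FormatError(f"family table missing columns {sorted(missing)}")
        self.frame = self.frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        dup = self.frame.duplicated(subset=["genome_id", "gene_id"])
        if dup.any():
            pair = self.frame.loc[dup.idxmax(), ["genome_id", "gene_id"]]
            raise FormatError(
                f"gene {pair['gene_id']!r} in genome {pair['genome_id']!r} "
                "is assigned to more than one family"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilyTable":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return cls(frame=frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def families(self) -> list[str]:
        return sorted(self.frame["family_id"].unique())

    def members(self, family_id: str) -> dict[str, list[str]]:
        """family -> {genome_id: [gene ids]} (paralogs allowed)."""
        sub = self.frame[self.frame["family_id"] == family_id]
        out: dict[str, list[str]] = {}
        for genome_id, genes in sub.groupby("genome_id")["gene_id"]:
            out[genome_id] = sorted(genes)
        return out

    def genomes_with(self, family_id: str) -> list[str]:
        sub = self.frame[self.frame["family_id"] == family_id]
        return sorted(sub["genome_id"].unique())


# ---------------------------------------------------------------------------
# Phylogeny


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths.

    Negative branch lengths and internal/leaf edges without a length are
    rejected; a missing root-edge length is tolerated (a stem is not part of
    the covariance structure).  A multifurcating root is accepted with a
    warning.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    validate_tree(tree, where=str(path))
    return tree


def validate_tree(tree: dendropy.Tree, where: str = "tree") -> None:
    for node in tree.preorder_node_iter():
        length = node.edge.length
        if node is tree.seed_node:
            continue
        if length is None:
            label = node.taxon.label if node.taxon else "<internal>"
            raise FormatError(f"{where}: missing branch length above {label}")
        if length < 0:
            label = node.taxon.label if node.taxon else "<internal>"
            raise FormatError(f"{where}: negative branch length above {label}")
    nchild = len(tree.seed_node.child_nodes())
    if nchild > 2:
        logger.warning("%s: root is multifurcating (%d children)", where, nchild)
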