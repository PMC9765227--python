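"""Genetic-code tables shared across the package.

Everything is derived from the bacterial/archaeal translation table
(NCBI table 11) at import time, so the 61 sense codons, the synonymous
families and the degeneracy classes used by the effective-number-of-codons
statistic are guaranteed mutually consistent.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

#: the 61 sense codons in fixed (lexicographic) order; all count vectors
#: and adaptiveness vectors in the package are indexed by this order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: amino acid -> tuple of synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, tuple())
for _aa in AA_TO_CODONS:
    AA_TO_CODONS[_aa] = tuple(sorted(c for c, a in CODON_TO_AA.items() if a == _aa))

#: amino acid -> degeneracy (number of synonymous codons)
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

#: degeneracy class -> amino acids in it (singletons Met/Trp excluded);
#: under table 11 this is 9 twofold, 1 threefold (Ile), 5 fourfold, 3 sixfold
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _k in DEGENERACY.items():
    if _k > 1:
        DEGENERACY_CLASSES.setdefault(_k, tuple())
for _k in DEGENERACY_CLASSES:
    DEGENERACY_CLASSES[_k] = tuple(sorted(a for a, d in DEGENERACY.items() if d == _k))

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def anticodon_of(codon: str) -> str:
    """The Watson-Crick anticodon (5'->3', DNA alphabet) of a codon."""
    return revcomp(codon)
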