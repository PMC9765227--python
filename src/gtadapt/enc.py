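"""Codon counting, GC3s, Wright's effective number of codons (ENC) and the
GC-corrected null expectation.

ENC measures how evenly a gene uses its synonymous codons: 20 means one
codon per amino acid (maximal bias), 61 means perfectly even usage (no
bias).  The null expectation given the gene's GC content at synonymous
third positions (GC3s) is the standard Nc-plot curve,
``2 + s + 29/(s^2 + (1-s)^2)``; a gene's deviation below that curve is the
codon-usage-bias score used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codes import (
    AA_TO_CODONS,
    CODON_INDEX,
    CODON_TO_AA,
    DEGENERACY_CLASSES,
    SENSE_CODONS,
    STOP_CODONS,
)

ENC_MIN = 20.0
ENC_MAX = 61.0

_ACGT = frozenset("ACGT")

# column indices of each amino acid's codons, precomputed once
_AA_COLS = {aa: np.array([CODON_INDEX[c] for c in codons])
            for aa, codons in AA_TO_CODONS.items() if len(codons) > 1}

# GC3s bookkeeping: synonymous codons (degeneracy >= 2) and, among those,
# the ones with G or C in third position
_SYN_MASK = np.array([len(AA_TO_CODONS[CODON_TO_AA[c]]) > 1 for c in SENSE_CODONS])
_GC3_MASK = np.array([c[2] in "GC" for c in SENSE_CODONS]) & _SYN_MASK


class CodonError(ValueError):
    """Raised for sequences that cannot be decomposed into codons."""


def count_codons(cds: str, gene_id: str = "<gene>") -> np.ndarray:
    """Count sense codons of a coding sequence.

    The terminal stop codon, if present, is stripped.  Codons containing
    characters outside A/C/G/T (e.g. N) are skipped, as are any internal
    stop codons; neither contributes to the total.  The sequence length
    must be divisible by 3 after stop stripping.

    Returns an integer vector over :data:`gtadapt.codes.SENSE_CODONS`.
    """
    seq = cds.upper()
    if len(seq) >= 3 and seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
    if len(seq) % 3 != 0:
        raise CodonError(f"{gene_id}: CDS length {len(seq)} not divisible by 3")
    counts = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        idx = CODON_INDEX.get(codon)
        if idx is not None:
            counts[idx] += 1
        # stop codons and codons with ambiguous bases are skipped
    return counts


def codon_count_frame(cds: dict[str, str]) -> pd.DataFrame:
    """Per-gene codon counts for a genome: genes x 61 sense codons."""
    data = {g: count_codons(s, gene_id=g) for g, s in cds.items()}
    frame = pd.DataFrame.from_dict(data, orient="index", columns=list(SENSE_CODONS))
    frame.index.name = "gene_id"
    return frame


def gc3s(counts: np.ndarray) -> float:
    """G+C fraction at third positions of synonymous codons.

    Only codons of amino acids with >=2 synonyms enter numerator and
    denominator (Met ATG and Trp TGG are excluded).  NaN when no
    synonymous codon was observed.
    """
    counts = np.asarray(counts)
    denom = counts[_SYN_MASK].sum()
    if denom == 0:
        return math.nan
    return float(counts[_GC3_MASK].sum() / denom)


def class_homozygosities(counts: np.ndarray) -> dict[int, float]:
    """Average codon homozygosity F per degeneracy class {2, 3, 4, 6}.

    For an amino acid with n observed codons (n >= 2) and usage fractions
    p, the homozygosity estimator is ``F = (n * sum(p^2) - 1) / (n - 1)``.
    Amino acids with n < 2 or F = 0 are omitted; a class with no usable
    amino acid is absent from the result.
    """
    counts = np.asarray(counts, dtype=float)
    per_class: dict[int, list[float]] = {}
    for aa, cols in _AA_COLS.items():
        n_a = counts[cols].sum()
        if n_a < 2:
            continue
        p = counts[cols] / n_a
        f_hat = (n_a * float(p @ p) - 1.0) / (n_a - 1.0)
        if f_hat <= 0:
            continue
        per_class.setdefault(len(cols), []).append(f_hat)
    return {k: float(np.mean(v)) for k, v in per_class.items()}


def enc_observed(counts: np.ndarray) -> float:
    """Wright's effective number of codons, capped into [20, 61].

    ``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6`` with class-average
    homozygosities.  A missing threefold class (Ile unobserved) is filled
    by Wright's convention F3 = (F2 + F4) / 2; if any other class is
    missing the statistic is undefined and NaN is returned.
    """
    fbar = class_homozygosities(counts)
    if 2 not in fbar or 4 not in fbar or 6 not in fbar:
        return math.nan
    if 3 not in fbar:
        fbar[3] = 0.5 * (fbar[2] + fbar[4])
    enc = 2.0
    for k, aas in DEGENERACY_CLASSES.items():
        enc += len(aas) / fbar[k]
    return float(min(ENC_MAX, max(ENC_MIN, enc)))


def enc_expected(s: float) -> float:
    """Expected ENC under no codon-usage bias at GC3s = s (Nc-plot null)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"gc3s must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_deviation(enc_obs: float, enc_exp: float) -> tuple[float, bool]:
    """Relative deviation of observed ENC below the null expectation.

    Returns ``((enc_exp - enc_obs) / enc_exp, excluded)`` where genes whose
    observed ENC exceeds the expectation are flagged for exclusion.
    """
    if not math.isfinite(enc_exp) or enc_exp <= 0:
        raise ValueError(f"invalid expected ENC {enc_exp}")
    deviation = (enc_exp - enc_obs) / enc_exp
    return deviation, enc_obs > enc_exp


@dataclass
class EncRecord:
    gene_id: str
    n_codons: int
    gc3s: float
    enc_obs: float
    enc_exp: float
    deviation: float
    excluded: bool


def enc_table(cds: dict[str, str]) -> pd.DataFrame:
    """Per-gene ENC report for one genome.

    Genes with undefined ENC (no usable degeneracy class) get NaN rows and
    ``excluded=True``.  Columns: n_codons, gc3s, enc_obs, enc_exp,
    deviation, excluded.
    """
    rows = []
    for gene_id, seq in cds.items():
        counts = count_codons(seq, gene_id=gene_id)
        n = int(counts.sum())
        s = gc3s(counts)
        obs = enc_observed(counts)
        if math.isnan(obs) or math.isnan(s):
            rows.append((gene_id, n, s, obs, math.nan, math.nan, True))
            continue
        exp = enc_expected(s)
        dev, excluded = enc_deviation(obs, exp)
        rows.append((gene_id, n, s, obs, exp, dev, excluded))
    frame = pd.DataFrame(
        rows,
        columns=["gene_id", "n_codons", "gc3s", "enc_obs", "enc_exp",
                 "deviation", "excluded"],
    ).set_index("gene_id")
    return frame
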