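"""tRNA adaptation index (tAI) from tRNA gene copy numbers.

Each codon's absolute adaptiveness W sums the copy numbers (tGCN) of the
tRNAs that can decode it, down-weighting non-Watson-Crick pairings by a
selective constraint s in [0, 1]:

    W(..U) = tGCN(A..) + (1 - s_GU) * tGCN(G..)
    W(..C) = tGCN(G..) + (1 - s_IC) * tGCN(A..)   (inosine at position 34)
    W(..A) = tGCN(U..) + (1 - s_IA) * tGCN(A..)
    W(..G) = tGCN(C..) + (1 - s_UG) * tGCN(U..)

with anticodons matched inside the codon's own four-codon box.  AUG is read
only by its Watson-Crick anticodon CAU; bacterial AUA (Ile) additionally
receives the lysidine-modified CAU tRNA with constraint s_LA.  A gene's
tAI is the geometric mean of its codons' relative adaptiveness w = W/max W,
and ptAI is the gene's within-genome percentile of tAI.

The constraints default to the classic values (G:U 0.41, I:C 0.28,
I:A 0.9999, U:G 0.68, L:A 0.89) and can be refined by a species-specific
coordinate-descent hill climb against a per-gene proxy of expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .codes import CODON_INDEX, SENSE_CODONS, revcomp
from .io import TrnaPool

logger = logging.getLogger(__name__)

#: the tunable wobble classes, in the fixed sweep order of the hill climb
WOBBLE_CLASSES = ("gu", "ic", "ia", "ug", "la")


@dataclass(frozen=True)
class WobbleWeights:
    """Selective constraints per pairing class (Watson-Crick fixed at 0)."""

    gu: float = 0.41
    ic: float = 0.28
    ia: float = 0.9999
    ug: float = 0.68
    la: float = 0.89
    provenance: str = "fixed-default"

    def __post_init__(self) -> None:
        for name in WOBBLE_CLASSES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"constraint {name}={v} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in WOBBLE_CLASSES}


DEFAULT_WOBBLE = WobbleWeights()

# wobble base of the anticodon pairing a given codon third base:
# (codon 3rd base) -> [(anticodon wobble base, constraint attribute)]
_PAIRINGS = {
    "T": (("A", None), ("G", "gu")),
    "C": (("G", None), ("A", "ic")),
    "A": (("T", None), ("A", "ia")),
    "G": (("C", None), ("T", "ug")),
}


def _tgcn(pool: TrnaPool, anticodon: str, isotype_prefix: str | None) -> float:
    if isotype_prefix is not None:
        by_iso = pool.isotype_count(anticodon, isotype_prefix)
        if by_iso is not None:
            return float(by_iso)
    return float(pool.count(anticodon))


def absolute_adaptiveness(
    pool: TrnaPool, s: WobbleWeights = DEFAULT_WOBBLE
) -> np.ndarray:
    """Absolute adaptiveness W per sense codon (order of SENSE_CODONS)."""
    W = np.zeros(len(SENSE_CODONS))
    for codon, idx in CODON_INDEX.items():
        tail = revcomp(codon[:2])  # anticodon positions 35-36
        if codon == "ATG":
            # elongator Met: Watson-Crick CAT only
            W[idx] = _tgcn(pool, "CAT", "Met")
            continue
        total = 0.0
        for wobble_base, constraint in _PAIRINGS[codon[2]]:
            anticodon = wobble_base + tail
            if codon == "ATA" and anticodon == "CAT":
                continue  # handled below via the lysidine pairing
            penalty = 0.0 if constraint is None else getattr(s, constraint)
            total += (1.0 - penalty) * _tgcn(pool, anticodon, None)
        if codon == "ATA":
            # lysidine-modified Ile2 tRNA (anticodon CAT) reads AUA
            total += (1.0 - s.la) * _tgcn(pool, "CAT", "Ile")
        W[idx] = total
    return W


def relative_adaptiveness(W: np.ndarray, replace_zeros: bool = True) -> np.ndarray:
    """w = W / max(W); zero entries replaced by the geometric mean of the
    nonzero w so per-gene geometric means stay positive.

    ``replace_zeros=False`` keeps zero entries at zero (useful when w acts
    as a sampling weight rather than an index component)."""
    W = np.asarray(W, dtype=float)
    wmax = W.max()
    if wmax <= 0:
        raise ValueError("tRNA pool gives zero adaptiveness for every codon")
    w = W / wmax
    nonzero = w > 0
    if replace_zeros and not nonzero.all():
        gm = float(np.exp(np.mean(np.log(w[nonzero]))))
        w = np.where(nonzero, w, gm)
    return w


def adaptiveness_table(
    pool: TrnaPool, s: WobbleWeights = DEFAULT_WOBBLE
) -> pd.DataFrame:
    """Per-codon absolute (W) and relative (w) adaptiveness."""
    W = absolute_adaptiveness(pool, s)
    w = relative_adaptiveness(W)
    return pd.DataFrame({"W": W, "w": w}, index=pd.Index(SENSE_CODONS, name="codon"))


def gene_tai(counts: np.ndarray, w: np.ndarray) -> float:
    """Geometric mean of w over the gene's codons (count-weighted)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("gene has no countable codons")
    return float(np.exp(counts @ np.log(w) / n))


def genome_tai(count_frame: pd.DataFrame, w: np.ndarray) -> pd.Series:
    """tAI for every gene of a genome from its codon-count frame."""
    counts = count_frame.to_numpy(dtype=float)
    n = counts.sum(axis=1)
    if (n <= 0).any():
        bad = count_frame.index[n <= 0][0]
        raise ValueError(f"gene {bad!r} has no countable codons")
    tai = np.exp(counts @ np.log(w) / n)
    return pd.Series(tai, index=count_frame.index, name="tai")


def ptai(tais: pd.Series) -> pd.Series:
    """Within-genome percentile of tAI in [0, 100).

    For each gene: 100 * (number of analyzed genes with strictly smaller
    tAI) / (number of analyzed genes).  Ties share the strict count; the
    genome minimum scores 0.
    """
    if len(tais) < 2:
        raise ValueError("ptAI needs at least 2 genes")
    values = tais.to_numpy(dtype=float)
    order = np.argsort(values, kind="mergesort")
    sorted_vals = values[order]
    # number of entries strictly smaller than each value
    smaller = np.searchsorted(sorted_vals, values, side="left")
    return pd.Series(100.0 * smaller / len(values), index=tais.index, name="ptai")


@dataclass
class OptimizeResult:
    weights: WobbleWeights
    objective: float
    converged: bool
    n_evaluations: int


def optimize_wobble(
    count_frame: pd.DataFrame,
    pool: TrnaPool,
    proxy: pd.Series,
    start: WobbleWeights = DEFAULT_WOBBLE,
    steps: tuple[float, ...] = (0.05, 0.01),
    max_sweeps: int = 200,
) -> OptimizeResult:
    """Species-specific wobble constraints by coordinate-descent hill climbing.

    Maximizes the Spearman correlation between per-gene tAI and ``proxy``
    (any per-gene expression surrogate; the ENC-deviation score is the
    default choice upstream).  Starting from ``start``, each constraint is
    perturbed by +/-step, coarse to fine ("maximum stringency" ends at step
    0.01), accepting moves that increase the objective, until no
    single-coordinate move improves.  Deterministic given the fixed sweep
    order.
    """
    common = count_frame.index.intersection(proxy.index)
    if len(common) < 30:
        raise ValueError(
            f"proxy defined for only {len(common)} genes; need at least 30"
        )
    counts = count_frame.loc[common]
    target = proxy.loc[common].to_numpy(dtype=float)
    if np.allclose(target, target[0]):
        raise ValueError("proxy is constant; objective undefined")

    n_eval = 0

    def objective(weights: WobbleWeights) -> float:
        nonlocal n_eval
        n_eval += 1
        w = relative_adaptiveness(absolute_adaptiveness(pool, weights))
        tai = genome_tai(counts, w)
        rho = stats.spearmanr(tai.to_numpy(), target).statistic
        return -np.inf if np.isnan(rho) else float(rho)

    current = replace(start, provenance="optimized")
    best = objective(current)
    converged = True
    for step in steps:
        for sweep in range(max_sweeps):
            improved = False
            for name in WOBBLE_CLASSES:
                base = getattr(current, name)
                for direction in (+1.0, -1.0):
                    cand_val = min(1.0, max(0.0, base + direction * step))
                    if cand_val == base:
                        continue
                    candidate = replace(current, **{name: cand_val})
                    score = objective(candidate)
                    if score > best:
                        current, best = candidate, score
                        improved = True
                        break
            if not improved:
                break
        else:
            logger.warning("hill climb hit the sweep limit at step %g", step)
            converged = False
    return OptimizeResult(current, best, converged, n_eval)
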