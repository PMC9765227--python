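"""Carbon cost of proteins and its association with translational adaptation.

The biosynthetic expense of a protein is proxied by the number of carbon
atoms in its amino acid side chains, normalized by protein length.  Side
chains only: the backbone contributes two carbons to every residue and is
uninformative; proline's three side-chain carbons are counted even though
its ring closes onto the backbone nitrogen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from scipy import stats

logger = logging.getLogger(__name__)

#: carbon atoms in each standard amino acid side chain
SIDE_CHAIN_CARBON: dict[str, int] = {
    "G": 0, "A": 1, "S": 1, "C": 1,
    "T": 2, "N": 2, "D": 2,
    "V": 3, "P": 3, "M": 3, "Q": 3, "E": 3,
    "L": 4, "I": 4, "K": 4, "R": 4, "H": 4,
    "F": 7, "Y": 7,
    "W": 9,
}


@dataclass
class CarbonCost:
    gene_id: str
    total: int
    length: int

    @property
    def per_residue(self) -> float:
        return self.total / self.length


def carbon_cost(protein: str, gene_id: str = "<protein>") -> CarbonCost:
    """Side-chain carbon count of a protein, total and per residue.

    Unknown residues (X) are skipped with a warning and do not count
    toward the length; an empty (or all-unknown) sequence is an error.
    """
    total = 0
    length = 0
    for aa in protein.upper().rstrip("*"):
        carbons = SIDE_CHAIN_CARBON.get(aa)
        if carbons is None:
            logger.warning("%s: unknown residue %r skipped", gene_id, aa)
            continue
        total += carbons
        length += 1
    if length == 0:
        raise ValueError(f"{gene_id}: no standard residues in protein sequence")
    return CarbonCost(gene_id=gene_id, total=total, length=length)


def carbon_cost_cds(cds: str, gene_id: str = "<gene>") -> CarbonCost:
    """Carbon cost of the protein encoded by a CDS (bacterial code)."""
    protein = str(Seq(cds).translate(table=11))
    return carbon_cost(protein, gene_id=gene_id)


@dataclass
class CorrelationResult:
    statistic: float
    p_value: float
    n: int
    method: str


def cost_vs_adaptation(costs, ptais) -> CorrelationResult:
    """Pearson correlation between per-residue carbon cost and ptAI.

    Both inputs must be aligned over the same genes (pandas Series are
    aligned by index).
    """
    costs = np.asarray(costs, dtype=float) if not hasattr(costs, "align") else costs
    if hasattr(costs, "align"):
        costs, ptais = costs.align(ptais, join="inner")
        costs = costs.to_numpy(dtype=float)
        ptais = ptais.to_numpy(dtype=float)
    else:
        ptais = np.asarray(ptais, dtype=float)
    if len(costs) != len(ptais) or len(costs) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.allclose(costs, costs[0]) or np.allclose(ptais, ptais[0]):
        raise ValueError("zero variance in one of the inputs")
    r = stats.pearsonr(costs, ptais)
    return CorrelationResult(float(r.statistic), float(r.pvalue), len(costs),
                             "pearson")
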