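"""Screen gene families whose within-genome tRNA-adaptation percentiles
(ptAI) track those of a reference gene set across genomes.

For every candidate family, its ptAI values across genomes are regressed
against each reference family's ptAI under phylogenetic GLS.  A family
found in >= 40 genomes passes only if the slope is significant against
*all* reference families; a rarer family (>= 10 genomes) qualifies only
when it sits inside the head-tail cluster regions and then needs
significance against at least 40% of the reference families.  Genomes with
paralogs contribute the median ptAI of their copies, and passing families
are revisited by refitting across paralog selections (exhaustively below
1000 combinations, otherwise 1000 seeded random draws).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FamilyTable
from .pgls import PGLS, TreeStructure, tree_structure

logger = logging.getLogger(__name__)

MIN_GENOMES_ALL_RULE = 40
MIN_GENOMES_CLUSTER_RULE = 10


def build_ptai_matrix(
    families: FamilyTable, ptai_by_genome: dict[str, pd.Series]
) -> pd.DataFrame:
    """Genomes x families matrix of ptAI values.

    A cell with a single family member carries that gene's ptAI; a cell
    with paralogs carries their median (midpoint of the central pair for
    even counts).  Families absent from a genome are NaN.
    """
    frame = families.frame
    values = np.empty(len(frame))
    for i, row in enumerate(frame.itertuples(index=False)):
        series = ptai_by_genome.get(row.genome_id)
        if series is None or row.gene_id not in series.index:
            raise KeyError(
                f"no ptAI value for gene {row.gene_id!r} in genome "
                f"{row.genome_id!r}"
            )
        values[i] = series[row.gene_id]
    long = frame.assign(ptai=values)
    matrix = long.pivot_table(
        index="genome_id", columns="family_id", values="ptai", aggfunc="median"
    )
    matrix.index.name = "genome_id"
    return matrix


class _PairFitter:
    """PGLS fits between matrix columns with per-tip-set structure caching."""

    def __init__(self, tree, matrix: pd.DataFrame):
        self.structure = (
            tree if isinstance(tree, TreeStructure) else tree_structure(tree)
        )
        self.matrix = matrix
        self._cache: dict[frozenset, TreeStructure] = {}

    def _pruned(self, tips: frozenset) -> TreeStructure:
        if tips not in self._cache:
            self._cache[tips] = self.structure.prune(tips)
        return self._cache[tips]

    def fit_pair(self, ycol: str, xcol: str):
        sub = self.matrix[[ycol, xcol]].dropna()
        tips = frozenset(sub.index)
        if len(tips) < 3:
            raise ValueError(
                f"families {ycol!r} and {xcol!r} share only {len(tips)} genomes"
            )
        structure = self._pruned(tips)
        model = PGLS(
            sub[ycol].to_numpy(), sub[xcol].to_numpy(), structure, list(sub.index)
        )
        return model.fit()

    def fit_vectors(self, y: pd.Series, xcol: str):
        sub = pd.concat([y.rename("__y__"), self.matrix[xcol]], axis=1).dropna()
        structure = self._pruned(frozenset(sub.index))
        model = PGLS(
            sub["__y__"].to_numpy(), sub[xcol].to_numpy(), structure, list(sub.index)
        )
        return model.fit()


def reference_pairwise(
    matrix: pd.DataFrame,
    reference: list[str],
    tree,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """PGLS between every unordered pair of reference families.

    Returns one row per pair with slope, p-value, transformation estimates
    and sample size.  A p-value of exactly 0 (machine underflow, e.g. for
    identical columns) is kept and flagged in the ``degenerate`` column.
    """
    rows = []
    fitter = _PairFitter(tree, matrix)
    for fam_a, fam_b in itertools.combinations(reference, 2):
        res = fitter.fit_pair(fam_a, fam_b)
        yvar = float(np.nanvar(matrix[fam_a].to_numpy(dtype=float)))
        degenerate = res.slope_p == 0.0 or res.sigma2 <= 1e-16 * max(yvar, 1e-300)
        rows.append(
            {
                "family_a": fam_a,
                "family_b": fam_b,
                "slope": res.slope,
                "p": res.slope_p,
                "lambda": res.lam,
                "delta": res.delta,
                "kappa": res.kappa,
                "n": res.nobs,
                "loglik": res.llf,
                "converged": res.converged,
                "significant": res.slope_p < alpha,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def flag_discordant_reference(
    pair_table: pd.DataFrame, alpha: float = 0.001, min_nonsig: int | None = None
) -> list[str]:
    """Reference families whose ptAI trend disagrees with the rest of the set.

    A family is flagged when it is non-significant (at ``alpha``) against at
    least ``min_nonsig`` of the other reference families; the default is
    two thirds of them, the proportion used to drop a discordant gene from
    the reference set.
    """
    families = sorted(set(pair_table["family_a"]) | set(pair_table["family_b"]))
    k = len(families) - 1
    if min_nonsig is None:
        min_nonsig = math.ceil(2 * k / 3)
    flagged = []
    for fam in families:
        sub = pair_table[
            (pair_table["family_a"] == fam) | (pair_table["family_b"] == fam)
        ]
        nonsig = int((sub["p"] >= alpha).sum())
        if nonsig >= min_nonsig:
            flagged.append(fam)
    return flagged


@dataclass
class ScreenResult:
    family_id: str
    n_genomes: int
    rule_applied: str  # "all-reference" | "forty-percent" | "not-screened"
    fits: pd.DataFrame = field(repr=False)  # per-reference slope/p
    passed: bool = False
    n_significant: int = 0
    robustness_fraction: float | None = None


def _required_hits(rule: str, k: int) -> int:
    return k if rule == "all-reference" else math.ceil(0.4 * k)


def _decide(
    fits: pd.DataFrame, n_genomes: int, in_cluster: bool, alpha: float
) -> tuple[str, bool, int]:
    k = len(fits)
    n_sig = int((fits["p"] < alpha).sum())
    if n_genomes >= MIN_GENOMES_ALL_RULE:
        return "all-reference", n_sig == k, n_sig
    if in_cluster and n_genomes >= MIN_GENOMES_CLUSTER_RULE:
        return "forty-percent", n_sig >= math.ceil(0.4 * k), n_sig
    return "not-screened", False, n_sig


def screen_family(
    matrix: pd.DataFrame,
    family: str,
    reference: list[str],
    tree,
    alpha: float = 0.05,
    in_cluster: bool = False,
    fitter: _PairFitter | None = None,
) -> ScreenResult:
    """Test one family's ptAI trend against every reference family."""
    missing = [r for r in reference if r not in matrix.columns]
    if missing:
        raise KeyError(f"reference families missing from matrix: {missing}")
    if family not in matrix.columns:
        raise KeyError(f"family {family!r} missing from matrix")
    if fitter is None:
        fitter = _PairFitter(tree, matrix)
    n_genomes = int(matrix[family].notna().sum())
    if n_genomes < MIN_GENOMES_CLUSTER_RULE or (
        n_genomes < MIN_GENOMES_ALL_RULE and not in_cluster
    ):
        fits = pd.DataFrame(columns=["reference", "slope", "p", "n"])
        return ScreenResult(family, n_genomes, "not-screened", fits)
    rows = []
    for ref in sorted(reference):
        res = fitter.fit_pair(family, ref)
        rows.append({"reference": ref, "slope": res.slope, "p": res.slope_p,
                     "n": res.nobs, "converged": res.converged})
    fits = pd.DataFrame(rows)
    rule, passed, n_sig = _decide(fits, n_genomes, in_cluster, alpha)
    return ScreenResult(family, n_genomes, rule, fits, passed, n_sig)


def screen_families(
    matrix: pd.DataFrame,
    candidates: list[str],
    reference: list[str],
    tree,
    alpha: float = 0.05,
    in_cluster: set[str] | None = None,
) -> pd.DataFrame:
    """Screen many families; one report row per family."""
    in_cluster = in_cluster or set()
    fitter = _PairFitter(tree, matrix)
    rows = []
    for family in sorted(candidates):
        result = screen_family(
            matrix, family, reference, tree, alpha=alpha,
            in_cluster=family in in_cluster, fitter=fitter,
        )
        rows.append(
            {
                "family_id": family,
                "n_genomes": result.n_genomes,
                "rule_applied": result.rule_applied,
                "n_significant": result.n_significant,
                "n_reference": len(reference),
                "passed": result.passed,
                "robustness_fraction": result.robustness_fraction,
            }
        )
    return pd.DataFrame(rows).set_index("family_id")


def paralog_combinations(members: dict[str, list[str]]) -> int:
    """Number of per-genome paralog selections for a family."""
    total = 1
    for genes in members.values():
        total *= len(genes)
    return total


def paralog_robustness(
    families: FamilyTable,
    ptai_by_genome: dict[str, pd.Series],
    matrix: pd.DataFrame,
    family: str,
    reference: list[str],
    tree,
    alpha: float = 0.05,
    in_cluster: bool = False,
    max_combinations: int = 1000,
    seed: int = 0,
) -> tuple[float, int, bool]:
    """Fraction of paralog selections under which the family still passes.

    Enumerates every per-genome choice of one paralog when the total number
    of combinations is below ``max_combinations``, otherwise draws exactly
    ``max_combinations`` seeded random selections.  Returns
    ``(fraction_passing, n_evaluated, enumerated)``.
    """
    members = families.members(family)
    genomes = sorted(members)
    choices = [members[g] for g in genomes]
    total = paralog_combinations(members)
    fitter = _PairFitter(tree, matrix)
    refs = sorted(reference)
    k = len(refs)
    n_genomes = int(matrix[family].notna().sum())

    def passes(selection: tuple[str, ...]) -> bool:
        y = pd.Series(
            [ptai_by_genome[g][gene] for g, gene in zip(genomes, selection)],
            index=genomes, dtype=float,
        )
        n_sig = 0
        for ref in refs:
            res = fitter.fit_vectors(y, ref)
            if res.slope_p < alpha:
                n_sig += 1
        rule, passed, _ = _decide(
            pd.DataFrame({"p": np.where(np.arange(k) < n_sig, 0.0, 1.0)}),
            n_genomes, in_cluster, alpha,
        )
        return passed

    if total < max_combinations:
        selections = list(itertools.product(*choices))
        enumerated = True
    else:
        rng = np.random.default_rng(seed)
        selections = [
            tuple(genes[rng.integers(len(genes))] for genes in choices)
            for _ in range(max_combinations)
        ]
        enumerated = False
    n_pass = sum(1 for sel in selections if passes(sel))
    return n_pass / len(selections), len(selections), enumerated
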