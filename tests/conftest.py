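"""Shared fixtures.

The default synthetic study (60 genomes, 12 reference + 10 planted + 200
null families) is expensive to screen, so it is generated and analyzed
once per session and shared by the end-to-end tests.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from gtadapt.enc import codon_count_frame
from gtadapt.screen import build_ptai_matrix, reference_pairwise, screen_families
from gtadapt.simulate import SimConfig, simulate_study
from gtadapt.tai import (
    DEFAULT_WOBBLE,
    absolute_adaptiveness,
    genome_tai,
    ptai,
    relative_adaptiveness,
)


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


@pytest.fixture
def three_tip_tree():
    return tree_from_newick("((A:1,B:1):1,C:2);")


def compute_ptai_tables(study):
    tables = {}
    for g, genome in study.genomes.items():
        counts = codon_count_frame(genome.cds)
        w = relative_adaptiveness(
            absolute_adaptiveness(genome.trna_pool, DEFAULT_WOBBLE)
        )
        tables[g] = ptai(genome_tai(counts, w))
    return tables


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study bundle (seeded)."""
    return simulate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_study_screen(default_study):
    """Full analysis of the default study: ptAI matrix, reference pairwise
    PGLS table and the genome-wide screen report."""
    study = default_study
    ptai_tables = compute_ptai_tables(study)
    matrix = build_ptai_matrix(study.families, ptai_tables)
    pairwise = reference_pairwise(matrix, study.reference, study.tree)
    candidates = [f for f in matrix.columns if f not in set(study.reference)]
    report = screen_families(matrix, candidates, study.reference, study.tree)
    return {
        "study": study,
        "ptai_tables": ptai_tables,
        "matrix": matrix,
        "pairwise": pairwise,
        "report": report,
    }


@pytest.fixture(scope="session")
def yule100_structure():
    """A 100-tip Yule tree's edge structure plus a Brownian Cholesky factor,
    shared by the PGLS calibration tests."""
    from gtadapt.pgls import tree_structure
    from gtadapt.simulate import simulate_tree

    tree = simulate_tree(100, seed=101)
    structure = tree_structure(tree)
    chol = np.linalg.cholesky(structure.covariance())
    return structure, chol
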