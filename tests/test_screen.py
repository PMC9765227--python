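"""The ptAI matrix, the reference-set validation and the family screen.

Trait-level fixtures: instead of simulating sequences, these tests build
ptAI-like percentile matrices directly from latent traits on a tree, which
isolates the decision logic from the sequence machinery.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from gtadapt.io import FamilyTable
from gtadapt.screen import (
    build_ptai_matrix,
    flag_discordant_reference,
    paralog_combinations,
    paralog_robustness,
    reference_pairwise,
    screen_families,
    screen_family,
)
from gtadapt.simulate import simulate_tree
from gtadapt.pgls import tree_structure


def _percentile(values: np.ndarray) -> np.ndarray:
    return 100.0 * (rankdata(values, method="ordinal") - 1) / len(values)


def planted_matrix(n_genomes=60, k_ref=8, n_noise=3, noise_sd=0.15, seed=5):
    """Percentile matrix whose REF columns share one latent trait and whose
    NOISE columns are independent."""
    tree = simulate_tree(n_genomes, seed=seed)
    structure = tree_structure(tree)
    chol = np.linalg.cholesky(structure.covariance())
    rng = np.random.default_rng(seed)
    shared = chol @ rng.standard_normal(n_genomes) + rng.normal(
        0, 0.6, n_genomes
    )
    columns = {}
    for i in range(k_ref):
        columns[f"REF{i:02d}"] = _percentile(
            shared + rng.normal(0, noise_sd, n_genomes)
        )
    for i in range(n_noise):
        own = chol @ rng.standard_normal(n_genomes) + rng.normal(
            0, 0.6, n_genomes
        )
        columns[f"NOISE{i:02d}"] = _percentile(own)
    matrix = pd.DataFrame(columns, index=list(structure.labels))
    matrix.index.name = "genome_id"
    return tree, matrix


@pytest.fixture(scope="module")
def planted():
    tree, matrix = planted_matrix()
    refs = [c for c in matrix.columns if c.startswith("REF")]
    return tree, matrix, refs


# --- ptAI matrix -----------------------------------------------------------


def make_family_table(rows):
    return FamilyTable(
        frame=pd.DataFrame(rows, columns=["genome_id", "family_id", "gene_id"])
    )


def test_build_ptai_matrix_median_paralog_policy():
    families = make_family_table(
        [
            ("G1", "F1", "a"), ("G1", "F1", "b"), ("G1", "F1", "c"),
            ("G2", "F1", "d"), ("G2", "F1", "e"),
            ("G3", "F1", "f"),
            ("G1", "F2", "g"),
        ]
    )
    ptais = {
        "G1": pd.Series({"a": 10.0, "b": 30.0, "c": 80.0, "g": 55.0}),
        "G2": pd.Series({"d": 10.0, "e": 30.0}),
        "G3": pd.Series({"f": 55.0}),
    }
    matrix = build_ptai_matrix(families, ptais)
    assert matrix.loc["G1", "F1"] == 30.0  # odd count: middle value
    assert matrix.loc["G2", "F1"] == 20.0  # even count: midpoint
    assert matrix.loc["G3", "F1"] == 55.0  # single member
    assert np.isnan(matrix.loc["G2", "F2"])  # family absent


def test_build_ptai_matrix_errors_on_missing_gene():
    families = make_family_table([("G1", "F1", "a")])
    with pytest.raises(KeyError, match="'a'"):
        build_ptai_matrix(families, {"G1": pd.Series({"b": 5.0})})


# --- reference pairwise ----------------------------------------------------


def test_reference_pairwise_all_significant_for_shared_trait(planted):
    tree, matrix, refs = planted
    table = reference_pairwise(matrix, refs, tree, alpha=0.05)
    assert len(table) == len(refs) * (len(refs) - 1) // 2
    assert (table["p"] < 0.05).all()
    assert (table["slope"] > 0).all()


def test_noise_reference_gene_is_flagged_discordant(planted):
    tree, matrix, refs = planted
    polluted = refs + ["NOISE00"]
    table = reference_pairwise(matrix, polluted, tree, alpha=0.001)
    flagged = flag_discordant_reference(table, alpha=0.001)
    assert "NOISE00" in flagged
    assert not any(r in flagged for r in refs)


def test_identical_columns_flagged_degenerate(planted):
    tree, matrix, refs = planted
    twin = matrix.copy()
    twin["TWIN"] = twin[refs[0]]
    table = reference_pairwise(twin, [refs[0], refs[1], "TWIN"], tree)
    row = table[(table.family_a == refs[0]) & (table.family_b == "TWIN")].iloc[0]
    assert row["slope"] == pytest.approx(1.0, abs=1e-8)
    assert row["degenerate"]


# --- family screen ---------------------------------------------------------


def test_screen_passes_planted_family_with_all_reference_rule(planted):
    tree, matrix, refs = planted
    rng = np.random.default_rng(17)
    planted_col = _percentile(
        rankdata(matrix[refs[0]]) + rng.normal(0, 2.0, len(matrix))
    )
    augmented = matrix.copy()
    augmented["CAND"] = planted_col
    result = screen_family(augmented, "CAND", refs, tree, alpha=0.05)
    assert result.rule_applied == "all-reference"
    assert result.passed
    assert result.n_significant == len(refs)


def test_screen_rejects_independent_noise_family(planted):
    tree, matrix, refs = planted
    result = screen_family(matrix, "NOISE01", refs, tree, alpha=0.05)
    assert result.rule_applied == "all-reference"
    assert not result.passed


def test_screen_rules_by_prevalence_and_cluster_flag(planted):
    tree, matrix, refs = planted
    sparse = matrix.copy()
    sparse["RARE"] = matrix["NOISE01"].where(
        np.arange(len(matrix)) < 20, np.nan
    )
    assert (
        screen_family(sparse, "RARE", refs, tree).rule_applied == "not-screened"
    )
    assert (
        screen_family(sparse, "RARE", refs, tree, in_cluster=True).rule_applied
        == "forty-percent"
    )
    very_rare = matrix.copy()
    very_rare["VR"] = matrix["NOISE01"].where(np.arange(len(matrix)) < 9, np.nan)
    result = screen_family(very_rare, "VR", refs, tree, in_cluster=True)
    assert result.rule_applied == "not-screened"


def test_forty_percent_rule_on_small_cluster_family():
    # 12 genomes, 12 reference genes: "at least 40%" of 12 rounds up to 5
    tree, matrix = planted_matrix(n_genomes=12, k_ref=12, noise_sd=0.05, seed=9)
    refs = [c for c in matrix.columns if c.startswith("REF")]
    rng = np.random.default_rng(1)
    matrix["CAND"] = _percentile(
        rankdata(matrix[refs[0]]) + rng.normal(0, 0.5, len(matrix))
    )
    result = screen_family(matrix, "CAND", refs, tree, in_cluster=True)
    assert result.rule_applied == "forty-percent"
    assert result.passed
    assert result.n_significant >= 5


def test_screen_order_invariance(planted):
    tree, matrix, refs = planted
    shuffled_matrix = matrix.sample(frac=1.0, random_state=4)
    shuffled_refs = list(reversed(refs))
    a = screen_family(matrix, "NOISE01", refs, tree)
    b = screen_family(shuffled_matrix, "NOISE01", shuffled_refs, tree)
    assert a.passed == b.passed
    assert a.n_significant == b.n_significant
    pd.testing.assert_frame_equal(
        a.fits.reset_index(drop=True), b.fits.reset_index(drop=True)
    )


def test_lowering_alpha_only_removes_passes(planted):
    tree, matrix, refs = planted
    rng = np.random.default_rng(17)
    augmented = matrix.copy()
    augmented["CAND"] = _percentile(
        rankdata(matrix[refs[0]]) + rng.normal(0, 8.0, len(matrix))
    )
    candidates = ["CAND", "NOISE01", "NOISE02"]
    loose = screen_families(augmented, candidates, refs, tree, alpha=0.05)
    strict = screen_families(augmented, candidates, refs, tree, alpha=1e-6)
    for fam in candidates:
        if strict.loc[fam, "passed"]:
            assert loose.loc[fam, "passed"]


def test_screen_missing_reference_errors(planted):
    tree, matrix, refs = planted
    with pytest.raises(KeyError, match="GHOST"):
        screen_family(matrix, "NOISE01", refs + ["GHOST"], tree)


# --- paralog robustness ----------------------------------------------------


def _paralog_setup(n_genomes, n_paralog_genomes, identical, seed=3):
    tree, matrix = planted_matrix(
        n_genomes=n_genomes, k_ref=2, n_noise=0, noise_sd=0.05, seed=seed
    )
    refs = [c for c in matrix.columns if c.startswith("REF")]
    genomes = list(matrix.index)
    rng = np.random.default_rng(seed)
    base = rankdata(matrix[refs[0]]) * 100.0 / len(genomes)
    rows, ptais = [], {}
    for i, g in enumerate(genomes):
        series = {}
        n_copies = 2 if i < n_paralog_genomes else 1
        for c in range(n_copies):
            gid = f"{g}_FAM_{c}"
            jitter = 0.0 if identical or c == 0 else rng.normal(0, 1.0)
            series[gid] = float(np.clip(base[i] + jitter, 0, 99.9))
            rows.append((g, "FAM", gid))
        ptais[g] = pd.Series(series)
    families = make_family_table(rows)
    matrix = matrix.copy()
    matrix["FAM"] = build_ptai_matrix(families, ptais)["FAM"]
    return families, ptais, matrix, refs, tree


def test_paralog_combinations_counted_exactly():
    members = {"G1": ["a", "b"], "G2": ["c", "d"], "G3": ["e", "f"]}
    assert paralog_combinations(members) == 8


def test_paralog_robustness_enumerates_small_cases():
    families, ptais, matrix, refs, tree = _paralog_setup(
        n_genomes=12, n_paralog_genomes=3, identical=False
    )
    frac, n_eval, enumerated = paralog_robustness(
        families, ptais, matrix, "FAM", refs, tree, in_cluster=True
    )
    assert enumerated
    assert n_eval == 8  # 2^3 selections


def test_paralog_robustness_draws_exactly_1000_when_large():
    families, ptais, matrix, refs, tree = _paralog_setup(
        n_genomes=11, n_paralog_genomes=11, identical=False
    )
    frac, n_eval, enumerated = paralog_robustness(
        families, ptais, matrix, "FAM", refs, tree, in_cluster=True, seed=7
    )
    assert not enumerated
    assert n_eval == 1000  # 2^11 = 2048 > 1000 -> seeded draws
    again = paralog_robustness(
        families, ptais, matrix, "FAM", refs, tree, in_cluster=True, seed=7
    )
    assert again[0] == frac  # seeded determinism


def test_paralog_robustness_identical_paralogs_fraction_one():
    families, ptais, matrix, refs, tree = _paralog_setup(
        n_genomes=12, n_paralog_genomes=4, identical=True
    )
    base = screen_family(matrix, "FAM", refs, tree, in_cluster=True)
    assert base.passed
    frac, n_eval, enumerated = paralog_robustness(
        families, ptais, matrix, "FAM", refs, tree, in_cluster=True
    )
    assert enumerated and n_eval == 16
    assert frac == 1.0
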