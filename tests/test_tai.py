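"""tRNA adaptiveness, tAI, ptAI and the wobble-constraint hill climb."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gtadapt.codes import CODON_INDEX, SENSE_CODONS
from gtadapt.enc import codon_count_frame, count_codons
from gtadapt.io import TrnaPool
from gtadapt.simulate import simulate_cds, simulate_trna_pool
from gtadapt.tai import (
    DEFAULT_WOBBLE,
    WobbleWeights,
    absolute_adaptiveness,
    gene_tai,
    genome_tai,
    optimize_wobble,
    ptai,
    relative_adaptiveness,
)


# --- absolute adaptiveness -------------------------------------------------


def test_phe_box_with_single_gaa_trna():
    W = absolute_adaptiveness(TrnaPool(counts={"GAA": 2}), DEFAULT_WOBBLE)
    assert W[CODON_INDEX["TTC"]] == pytest.approx(2.0)
    assert W[CODON_INDEX["TTT"]] == pytest.approx((1 - 0.41) * 2)


def test_box_without_trnas_gets_zero():
    W = absolute_adaptiveness(TrnaPool(counts={"GAA": 2}), DEFAULT_WOBBLE)
    assert W[CODON_INDEX["GGG"]] == 0.0


def test_full_constraints_leave_watson_crick_only():
    strict = WobbleWeights(gu=1, ic=1, ia=1, ug=1, la=1)
    pool = TrnaPool(counts={"GAA": 2, "AAA": 3})
    W = absolute_adaptiveness(pool, strict)
    assert W[CODON_INDEX["TTC"]] == 2.0  # G:C Watson-Crick
    assert W[CODON_INDEX["TTT"]] == 3.0  # A:T Watson-Crick only


def test_atg_uses_only_watson_crick_cat():
    pool = TrnaPool(counts={"CAT": 3, "TAT": 5})
    W = absolute_adaptiveness(pool, DEFAULT_WOBBLE)
    assert W[CODON_INDEX["ATG"]] == 3.0


def test_ata_receives_lysidine_cat_contribution():
    pool = TrnaPool(counts={"CAT": 4})
    W = absolute_adaptiveness(pool, DEFAULT_WOBBLE)
    assert W[CODON_INDEX["ATA"]] == pytest.approx((1 - 0.89) * 4)


def test_isotype_labels_split_cat_between_met_and_ile2():
    pool = TrnaPool(
        counts={"CAT": 4},
        isotypes={"CAT": {"Met": 3, "Ile2": 1}},
    )
    W = absolute_adaptiveness(pool, DEFAULT_WOBBLE)
    assert W[CODON_INDEX["ATG"]] == 3.0
    assert W[CODON_INDEX["ATA"]] == pytest.approx((1 - 0.89) * 1)


# --- relative adaptiveness -------------------------------------------------


def test_relative_adaptiveness_zero_replacement():
    w = relative_adaptiveness(np.array([4.0, 2.0, 0.0]))
    assert w[0] == 1.0
    assert w[1] == 0.5
    assert w[2] == pytest.approx(np.sqrt(0.5))


def test_relative_adaptiveness_raw_mode_keeps_zeros():
    w = relative_adaptiveness(np.array([4.0, 2.0, 0.0]), replace_zeros=False)
    assert w[2] == 0.0


def test_relative_adaptiveness_single_nonzero_and_scaling():
    w = relative_adaptiveness(np.array([0.0, 3.0, 0.0]))
    assert w[1] == 1.0
    a = relative_adaptiveness(np.array([1.0, 2.0, 5.0]))
    b = relative_adaptiveness(np.array([10.0, 20.0, 50.0]))
    np.testing.assert_allclose(a, b)


def test_relative_adaptiveness_all_zero_errors():
    with pytest.raises(ValueError, match="zero adaptiveness"):
        relative_adaptiveness(np.zeros(4))


# --- gene tAI --------------------------------------------------------------


def test_gene_tai_examples():
    w = np.ones(61)
    counts = np.zeros(61)
    counts[:3] = 5
    assert gene_tai(counts, w) == 1.0

    w2 = np.ones(61)
    w2[0], w2[1] = 0.25, 1.0
    counts2 = np.zeros(61)
    counts2[0] = counts2[1] = 7
    assert gene_tai(counts2, w2) == pytest.approx(0.5, abs=1e-12)

    w3 = np.ones(61)
    w3[0], w3[1] = 1.0, 0.5
    counts3 = np.zeros(61)
    counts3[0], counts3[1] = 3, 1
    assert gene_tai(counts3, w3) == pytest.approx(0.5**0.25, abs=1e-12)


def test_gene_tai_matches_naive_product():
    rng = np.random.default_rng(7)
    for _ in range(25):
        counts = rng.integers(0, 8, size=61)
        if counts.sum() == 0:
            continue
        w = rng.uniform(0.05, 1.0, size=61)
        naive = np.prod([w[i] ** counts[i] for i in range(61)]) ** (
            1.0 / counts.sum()
        )
        assert gene_tai(counts, w) == pytest.approx(naive, rel=1e-12)


def test_tai_invariant_to_pool_scaling():
    rng = np.random.default_rng(21)
    pool = simulate_trna_pool(rng)
    scaled = TrnaPool(counts={a: 7 * n for a, n in pool.counts.items()})
    w1 = relative_adaptiveness(absolute_adaptiveness(pool, DEFAULT_WOBBLE))
    w2 = relative_adaptiveness(absolute_adaptiveness(scaled, DEFAULT_WOBBLE))
    np.testing.assert_allclose(w1, w2)


# --- ptAI ------------------------------------------------------------------


def test_ptai_examples():
    tais = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
    p = ptai(tais)
    assert p["a"] == 0.0
    assert p["d"] == 75.0


def test_ptai_ties_share_strict_count():
    tais = pd.Series([0.1, 0.2, 0.5, 0.5], index=list("abcd"))
    p = ptai(tais)
    assert p["c"] == p["d"] == 50.0


def test_ptai_is_rank_preserving():
    rng = np.random.default_rng(3)
    tais = pd.Series(rng.uniform(0, 1, 50))
    p = ptai(tais)
    assert (p.rank() == tais.rank()).all()
    assert (p >= 0).all() and (p < 100).all()


def test_ptai_needs_two_genes():
    with pytest.raises(ValueError):
        ptai(pd.Series([0.5]))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_ptai_bounds_property(seed):
    rng = np.random.default_rng(seed)
    tais = pd.Series(rng.uniform(0.01, 1, size=rng.integers(2, 40)))
    p = ptai(tais)
    assert p.min() == 0.0
    assert (p < 100).all()


# --- generator recovery ----------------------------------------------------


def test_ptai_tracks_planted_selection_strength():
    """Within one genome, ptAI recovers the planted ranking of selection
    strengths (Spearman > 0.8 at 500 genes)."""
    from scipy.stats import spearmanr

    rng = np.random.default_rng(11)
    pool = simulate_trna_pool(rng)
    w_raw = relative_adaptiveness(
        absolute_adaptiveness(pool, DEFAULT_WOBBLE), replace_zeros=False
    )
    s_values = rng.uniform(0, 1, 500)
    cds = {
        f"g{i}": simulate_cds(float(s), 300, pool, 0.55, rng, w=w_raw)
        for i, s in enumerate(s_values)
    }
    counts = codon_count_frame(cds)
    w = relative_adaptiveness(absolute_adaptiveness(pool, DEFAULT_WOBBLE))
    p = ptai(genome_tai(counts, w))
    assert spearmanr(s_values, p.to_numpy()).statistic > 0.8


# --- wobble optimization ---------------------------------------------------


def _study_for_optimizer(seed=11, n_genes=400, gu=0.6, ug=0.3):
    rng = np.random.default_rng(seed)
    pool = simulate_trna_pool(rng)
    s_true = WobbleWeights(gu=gu, ug=ug)
    w_true_raw = relative_adaptiveness(
        absolute_adaptiveness(pool, s_true), replace_zeros=False
    )
    s_values = rng.uniform(0, 1, n_genes)
    cds = {
        f"g{i}": simulate_cds(float(s), 300, pool, 0.55, rng, w=w_true_raw)
        for i, s in enumerate(s_values)
    }
    counts = codon_count_frame(cds)
    w_true = relative_adaptiveness(absolute_adaptiveness(pool, s_true))
    proxy = genome_tai(counts, w_true)  # the planted adaptation itself
    return counts, pool, proxy, s_true


def test_hill_climb_never_worsens_the_objective():
    counts, pool, proxy, _ = _study_for_optimizer(n_genes=120)
    from scipy.stats import spearmanr

    w0 = relative_adaptiveness(absolute_adaptiveness(pool, DEFAULT_WOBBLE))
    baseline = spearmanr(
        genome_tai(counts, w0).to_numpy(), proxy.loc[counts.index].to_numpy()
    ).statistic
    result = optimize_wobble(counts, pool, proxy)
    assert result.objective >= baseline


def test_hill_climb_recovers_planted_constraints():
    counts, pool, proxy, s_true = _study_for_optimizer()
    result = optimize_wobble(counts, pool, proxy, steps=(0.1, 0.05, 0.01))
    assert abs(result.weights.gu - s_true.gu) <= 0.1
    assert abs(result.weights.ug - s_true.ug) <= 0.1


def test_hill_climb_rejects_constant_proxy():
    counts, pool, _, _ = _study_for_optimizer(n_genes=60)
    constant = pd.Series(1.0, index=counts.index)
    with pytest.raises(ValueError, match="constant"):
        optimize_wobble(counts, pool, constant)


def test_hill_climb_requires_thirty_genes():
    counts, pool, proxy, _ = _study_for_optimizer(n_genes=60)
    with pytest.raises(ValueError, match="at least 30"):
        optimize_wobble(counts.iloc[:10], pool, proxy.iloc[:10])
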