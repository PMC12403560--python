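"""Profile binarization, phi correlation, co-loss mining and enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from regloss import (
    ABSENT,
    PRESENT_CONSERVED_SEED,
    PRESENT_DIVERGENT_SEED,
    ProfileMatrix,
    binarize,
    dollo_loss_report,
    fisher_enrichment,
    mine_coloss,
    pearson_binary,
    rank_and_cut,
    ubiquity_filter,
)


def phi_oracle(u, v):
    """Phi coefficient from the 2x2 co-occurrence table (closed form)."""
    u, v = np.asarray(u), np.asarray(v)
    n11 = int(((u == 1) & (v == 1)).sum())
    n10 = int(((u == 1) & (v == 0)).sum())
    n01 = int(((u == 0) & (v == 1)).sum())
    n00 = int(((u == 0) & (v == 0)).sum())
    denom = math.sqrt(
        (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    )
    if denom == 0:
        return None
    return (n11 * n00 - n10 * n01) / denom


# ---------------------------------------------------------------------------
# binarization


def test_binarize_divergent_seed_counts_as_absent_by_default():
    pm = ProfileMatrix(
        pd.DataFrame(
            [[PRESENT_CONSERVED_SEED, PRESENT_DIVERGENT_SEED, ABSENT]],
            index=["mirX"],
            columns=["t1", "t2", "t3"],
        )
    )
    assert binarize(pm).loc["mirX"].tolist() == [1, 0, 0]
    assert binarize(pm, divergent_as_absent=False).loc["mirX"].tolist() == [1, 1, 0]


# ---------------------------------------------------------------------------
# phi / Pearson


@pytest.mark.parametrize(
    "u,v,expected",
    [
        ([1, 0, 1, 1, 0], [1, 0, 1, 1, 0], 1.0),
        ([1, 0, 1], [0, 1, 0], -1.0),
        ([1, 1, 0, 0], [1, 0, 1, 0], 0.0),
    ],
)
def test_pearson_binary_reference_values(u, v, expected):
    assert pearson_binary(u, v) == pytest.approx(expected)


def test_pearson_binary_undefined_for_constant_vectors():
    assert pearson_binary([1, 1, 1], [1, 0, 1]) is None
    assert pearson_binary([1, 0, 1], [0, 0, 0]) is None


def test_pearson_binary_length_mismatch_raises():
    with pytest.raises(ValueError, match="length"):
        pearson_binary([1, 0], [1, 0, 1])


def test_pearson_equals_phi_on_all_corner_tables():
    """Every pair of length-4 binary vectors (covers all 2x2 corner tables)."""
    for u in itertools.product((0, 1), repeat=4):
        for v in itertools.product((0, 1), repeat=4):
            expected = phi_oracle(u, v)
            got = pearson_binary(u, v)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.lists(st.booleans(), min_size=2, max_size=20),
    st.data(),
)
def test_pearson_equals_phi_on_random_vectors(u, data):
    v = data.draw(st.lists(st.booleans(), min_size=len(u), max_size=len(u)))
    ui, vi = [int(x) for x in u], [int(x) for x in v]
    expected = phi_oracle(ui, vi)
    got = pearson_binary(ui, vi)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# ranking and mining


def _binary_df(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


def test_rank_and_cut_top_percentile_count():
    rng = np.random.default_rng(5)
    mirna = pd.Series(rng.integers(0, 2, size=30))
    genes = {}
    for i in range(200):
        # distinct r values: add i-dependent noise pattern
        v = mirna.copy()
        flips = rng.choice(30, size=1 + i % 15, replace=False)
        v.iloc[flips] = 1 - v.iloc[flips]
        genes[f"g{i:03d}"] = v.tolist()
    df = _binary_df(genes)
    hits = rank_and_cut(df, mirna, percentile=1.0)
    assert len(hits) >= 2  # ceil(200 * 1%) = 2, plus any ties at the cutoff


def test_rank_and_cut_includes_all_ties_at_cutoff():
    mirna = pd.Series([1, 0, 1, 0, 1, 0])
    genes = _binary_df(
        {
            "tie1": [1, 0, 1, 0, 1, 0],
            "tie2": [1, 0, 1, 0, 1, 0],
            "tie3": [1, 0, 1, 0, 1, 0],
            "far": [0, 1, 0, 1, 0, 1],
        }
    )
    hits = rank_and_cut(genes, mirna, percentile=1.0)  # nominal count: 1
    assert hits == {"tie1", "tie2", "tie3"}


def test_rank_and_cut_planted_identical_gene_ranks_first():
    rng = np.random.default_rng(7)
    mirna = pd.Series(rng.integers(0, 2, size=40))
    genes = {f"bg{i:02d}": rng.integers(0, 2, size=40).tolist() for i in range(99)}
    genes["planted"] = mirna.tolist()
    hits = rank_and_cut(_binary_df(genes), mirna, percentile=1.0)
    assert "planted" in hits


def test_rank_and_cut_all_constant_is_an_error():
    mirna = pd.Series([1, 0, 1])
    genes = _binary_df({"a": [1, 1, 1], "b": [0, 0, 0]})
    with pytest.raises(ValueError, match="no rankable"):
        rank_and_cut(genes, mirna)


def test_mine_coloss_majority_rule_rounds_up():
    """With 15 miRNAs, 'at least half' means 8 supporting profiles."""
    rng = np.random.default_rng(11)
    base = pd.Series(rng.integers(0, 2, size=40))
    mirnas = {}
    for i in range(15):
        v = base.copy()
        v.iloc[rng.choice(40, size=2, replace=False)] = rng.integers(0, 2, size=2)
        if v.nunique() == 1:
            v.iloc[0] = 1 - v.iloc[0]
        mirnas[f"mir{i:02d}"] = v.tolist()
    mirna_df = _binary_df(mirnas)
    genes = {f"bg{i:03d}": rng.integers(0, 2, size=40).tolist() for i in range(300)}
    genes["strong"] = base.tolist()
    result = mine_coloss(_binary_df(genes), mirna_df)
    assert (result["min_support"] == 8).all()


def test_mine_coloss_recovers_planted_set_without_noise():
    """Zero background noise: recovered set equals the planted set exactly."""
    rng = np.random.default_rng(42)
    n_taxa = 30
    pattern = np.ones(n_taxa, dtype=int)
    pattern[:6] = 0  # lost in the first six taxa
    mirnas = _binary_df({f"mir{i}": pattern.tolist() for i in range(5)})
    genes = {f"planted{i:02d}": pattern.tolist() for i in range(20)}
    for i in range(980):
        v = np.ones(n_taxa, dtype=int)
        v[rng.choice(np.arange(6, n_taxa), size=3, replace=False)] = 0
        genes[f"bg{i:03d}"] = v.tolist()
    result = mine_coloss(_binary_df(genes), mirnas, percentile=1.0, min_fraction=0.5)
    assert set(result["gene_id"]) == {f"planted{i:02d}" for i in range(20)}


def test_mine_coloss_monotone_in_fraction_and_percentile():
    rng = np.random.default_rng(13)
    genes = _binary_df(
        {f"g{i:03d}": rng.integers(0, 2, size=25).tolist() for i in range(150)}
    )
    mirnas = _binary_df(
        {f"m{i}": rng.integers(0, 2, size=25).tolist() for i in range(6)}
    )
    base = set(mine_coloss(genes, mirnas, percentile=2.0, min_fraction=0.5)["gene_id"])
    lower_frac = set(
        mine_coloss(genes, mirnas, percentile=2.0, min_fraction=0.3)["gene_id"]
    )
    higher_pct = set(
        mine_coloss(genes, mirnas, percentile=5.0, min_fraction=0.5)["gene_id"]
    )
    assert base <= lower_frac
    assert base <= higher_pct


def test_mine_coloss_empty_mirna_set_is_an_error():
    genes = _binary_df({"g": [1, 0, 1]})
    with pytest.raises(ValueError):
        mine_coloss(genes, pd.DataFrame())


# ---------------------------------------------------------------------------
# Dollo loss report


def test_loss_report_all_present_gains_at_root_without_losses(fixture_tree):
    profile = {t: 1 for t in fixture_tree.taxa}
    rep = dollo_loss_report(profile, fixture_tree, gene_id="g")
    assert rep.gain_branch == fixture_tree.root.branch_id
    assert rep.n_independent_losses == 0


def test_loss_report_murid_absence_is_one_stem_loss(fixture_tree):
    profile = {t: 0 if t in {"Mouse", "Rat"} else 1 for t in fixture_tree.taxa}
    rep = dollo_loss_report(profile, fixture_tree)
    assert rep.loss_branches == ("Mouse+Rat",)
    assert rep.n_independent_losses == 1


def test_loss_report_single_leaf_presence(fixture_tree):
    profile = {t: int(t == "Dog") for t in fixture_tree.taxa}
    rep = dollo_loss_report(profile, fixture_tree)
    assert rep.gain_branch == "Dog"
    assert rep.n_independent_losses == 0


def test_loss_report_never_observed_is_an_error(fixture_tree):
    with pytest.raises(ValueError, match="never observed"):
        dollo_loss_report({t: 0 for t in fixture_tree.taxa}, fixture_tree)


# ---------------------------------------------------------------------------
# ubiquity filter and Fisher enrichment


def test_ubiquity_filter_strict_boundary():
    df = pd.DataFrame(
        {f"t{i}": [int(i >= 4), int(i >= 5), 1] for i in range(100)},
        index=["at96", "at95", "everywhere"],
    )
    ubiquitous, lost = ubiquity_filter(df, threshold=0.95)
    assert "at96" in ubiquitous  # 96/100 > 95%
    assert "at95" in lost  # 95/100 is not strictly greater
    assert "everywhere" in ubiquitous


def test_ubiquity_filter_zero_threshold():
    df = pd.DataFrame({"t1": [1, 0], "t2": [0, 0]}, index=["some", "none"])
    ubiquitous, lost = ubiquity_filter(df, threshold=0.0)
    assert ubiquitous == {"some"}
    assert lost == {"none"}


def test_fisher_enrichment_fold_and_exact_p():
    res = fisher_enrichment(5, 10, 10, 100)
    assert res.fold == pytest.approx(5.0)
    # independent oracle: two-sided exact p by hypergeometric enumeration
    rv = hypergeom(100, 10, 10)
    p_obs = rv.pmf(5)
    oracle = sum(rv.pmf(k) for k in range(11) if rv.pmf(k) <= p_obs * (1 + 1e-9))
    assert res.p == pytest.approx(oracle, rel=1e-6)


def test_fisher_enrichment_degenerate_cases():
    empty = fisher_enrichment(0, 10, 0, 100)
    assert empty.fold == 0.0 and empty.p == 1.0
    full = fisher_enrichment(7, 50, 7, 50)
    assert full.fold == pytest.approx(1.0) and full.p == 1.0


def test_fisher_enrichment_symmetric_under_table_transpose():
    # swapping rows with columns of the 2x2 table keeps the exact p
    a, s, h, n = 4, 12, 30, 200
    p1 = fisher_enrichment(a, s, h, n).p
    p2 = fisher_enrichment(a, h, s, n).p
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_fisher_enrichment_inconsistent_counts_raise():
    with pytest.raises(ValueError, match="inconsistent"):
        fisher_enrichment(5, 3, 10, 100)
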