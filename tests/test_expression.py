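"""DE classification, resampling enrichment and overlap significance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from regloss import (
    classify_de,
    expression_similarity_null,
    ortholog_overlap,
    overlap_significance,
    resample_enrichment,
)


def oracle_classify(table, lfc_min=0.5, reads_min=100, alpha=0.05):
    """Independent row-by-row re-implementation of the DE filters."""
    up, down, universe = set(), set(), set()
    for _, row in table.iterrows():
        if row["control_reads"] < reads_min or pd.isna(row["padj"]):
            continue
        universe.add(row["gene_id"])
        if row["padj"] > alpha:
            continue
        if row["log2fc"] > lfc_min:
            up.add(row["gene_id"])
        elif row["log2fc"] < -lfc_min:
            down.add(row["gene_id"])
    return up, down, universe


# ---------------------------------------------------------------------------
# DE classification


def _de_table(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "control_reads", "log2fc", "padj"]
    )


def test_classify_de_boundary_rules():
    table = _de_table(
        [
            ("down_ok", 150.0, -0.6, 0.01),
            ("lfc_at_boundary", 150.0, 0.5, 0.01),  # strict: excluded
            ("padj_at_alpha", 150.0, -0.9, 0.05),  # inclusive: down
            ("reads_low", 99.0, -0.9, 0.001),  # excluded from universe
            ("up_ok", 150.0, 0.8, 0.02),
            ("untested", 500.0, -2.0, float("nan")),  # no padj: not tested
        ]
    )
    sets = classify_de(table)
    assert sets.down == {"down_ok", "padj_at_alpha"}
    assert sets.up == {"up_ok"}
    assert "reads_low" not in sets.universe
    assert "untested" not in sets.universe
    assert "lfc_at_boundary" in sets.universe


def test_classify_de_matches_independent_oracle_on_random_table():
    rng = np.random.default_rng(20)
    n = 800
    table = _de_table(
        list(
            zip(
                [f"g{i}" for i in range(n)],
                rng.lognormal(np.log(200), 1.2, n).round(2),
                rng.normal(0, 1, n).round(3),
                np.where(rng.random(n) < 0.05, np.nan, rng.random(n)),
            )
        )
    )
    sets = classify_de(table)
    up, down, universe = oracle_classify(table)
    assert sets.up == up
    assert sets.down == down
    assert sets.universe == universe


# ---------------------------------------------------------------------------
# resampling enrichment


def test_resample_enrichment_all_targets_is_extreme():
    universe = [f"g{i}" for i in range(100)]
    targets = universe[:50]
    de_set = universe[:10]
    res = resample_enrichment(de_set, targets, universe, n=1000, seed=1)
    assert res.observed == 10
    # closed-form point probability of the most extreme table,
    # C(50,10)/C(100,10), computed directly as the product form
    point = np.prod([(50 - i) / (100 - i) for i in range(10)])
    assert hypergeom(100, 50, 10).pmf(10) == pytest.approx(point, rel=1e-9)
    assert point < 1e-3
    assert res.p_two_sided < 0.01
    assert res.p_exact < 0.01


def test_resample_enrichment_null_consistent_observation():
    rng = np.random.default_rng(2)
    universe = [f"g{i}" for i in range(200)]
    targets = universe[:100]
    de_set = list(rng.choice(universe, size=20, replace=False))
    res = resample_enrichment(de_set, targets, universe, n=2000, seed=3)
    expected = 20 * 0.5
    if abs(res.observed - expected) <= 1:
        assert abs(res.z) < 1.0
        assert res.p_two_sided > 0.3


def test_resample_enrichment_degenerate_universe_falls_back_to_exact():
    universe = [f"g{i}" for i in range(50)]
    res = resample_enrichment(universe[:5], universe, universe, n=100, seed=0)
    assert res.null_sd == 0.0
    assert res.p_two_sided == 1.0


def test_resample_enrichment_requires_subset():
    with pytest.raises(ValueError, match="universe"):
        resample_enrichment(["x"], ["a"], ["a", "b"], n=10, seed=0)


def test_resample_null_moments_match_hypergeometric():
    """Null mean and sd within 3 Monte-Carlo SEs of the closed form."""
    rng = np.random.default_rng(30)
    for _ in range(20):
        n_universe = int(rng.integers(60, 400))
        n_targets = int(rng.integers(10, n_universe // 2))
        k = int(rng.integers(10, n_universe // 3))
        universe = [f"g{i}" for i in range(n_universe)]
        targets = universe[:n_targets]
        de_set = universe[-k:]
        res = resample_enrichment(
            de_set, targets, universe, n=1000, seed=int(rng.integers(2**31))
        )
        rv = hypergeom(n_universe, n_targets, k)
        se_mean = rv.std() / np.sqrt(1000)
        assert abs(res.null_mean - rv.mean()) < 3 * se_mean
        se_sd = rv.std() / np.sqrt(2 * 999)
        assert abs(res.null_sd - rv.std()) < 4 * se_sd


def test_resample_enrichment_is_reproducible():
    universe = [f"g{i}" for i in range(100)]
    a = resample_enrichment(universe[:10], universe[:30], universe, n=500, seed=11)
    b = resample_enrichment(universe[:10], universe[:30], universe, n=500, seed=11)
    assert a == b


# ---------------------------------------------------------------------------
# overlap significance


def test_overlap_disjoint_small_sets_not_significant():
    universe = [f"g{i}" for i in range(1000)]
    a, b = universe[:10], universe[10:20]
    overlap, p = overlap_significance(a, b, universe, method="fisher")
    assert overlap == 0
    assert p > 0.5


def test_overlap_identical_sets_hits_the_empirical_floor():
    universe = [f"g{i}" for i in range(1000)]
    a = universe[:10]
    overlap, p_f = overlap_significance(a, a, universe, method="fisher")
    assert overlap == 10
    # hypergeometric tail oracle: probability of full overlap by chance
    assert hypergeom(1000, 10, 10).sf(9) < 1e-20
    _, p_e = overlap_significance(a, a, universe, method="empirical",
                                  n=1_000_000, seed=5)
    assert p_e == pytest.approx(1 / (1_000_000 + 1))
    assert p_f < 1e-20


def test_empirical_p_is_never_zero_and_reproducible():
    universe = [f"g{i}" for i in range(300)]
    a, b = universe[:30], universe[20:60]
    _, p1 = overlap_significance(a, b, universe, "empirical", n=10_000, seed=9)
    _, p2 = overlap_significance(a, b, universe, "empirical", n=10_000, seed=9)
    assert p1 == p2 > 0


def test_empirical_p_matches_hypergeometric_tail():
    rng = np.random.default_rng(40)
    universe = [f"g{i}" for i in range(500)]
    for _ in range(10):
        a = list(rng.choice(universe, size=40, replace=False))
        b = list(rng.choice(universe, size=60, replace=False))
        observed, p_e = overlap_significance(
            a, b, universe, "empirical", n=100_000, seed=int(rng.integers(2**31))
        )
        tail = hypergeom(500, 60, 40).sf(observed - 1)
        se = np.sqrt(tail * (1 - tail) / 100_000)
        assert abs(p_e - tail) < 3 * se + 2 / 100_000


def test_overlap_empty_universe_is_an_error():
    with pytest.raises(ValueError, match="universe"):
        overlap_significance(["a"], ["a"], [], "fisher")


# ---------------------------------------------------------------------------
# ortholog overlap


def test_ortholog_overlap_maps_namespaces():
    universe = [f"H{i}" for i in range(100)]
    human = set(universe[:10])
    mouse = {f"m{i}" for i in range(5, 15)}
    mapping = {f"m{i}": f"H{i}" for i in range(100)}
    shared, p = ortholog_overlap(human, mouse, mapping, universe, method="fisher")
    assert shared == [f"H{i}" for i in range(5, 10)]
    assert p < 0.01


def test_ortholog_overlap_unmapped_genes_dropped():
    universe = [f"H{i}" for i in range(50)]
    shared, p = ortholog_overlap(
        set(universe[:5]), {"m1", "m2"}, {}, universe, method="fisher"
    )
    assert shared == []
    assert p == 1.0


def test_ortholog_overlap_rejects_many_to_one_map():
    with pytest.raises(ValueError, match="1:1"):
        ortholog_overlap({"H1"}, {"m1"}, {"m1": "H1", "m2": "H1"}, ["H1"], "fisher")


def test_ortholog_overlap_recovers_planted_shared_targets():
    rng = np.random.default_rng(50)
    universe = [f"H{i:03d}" for i in range(400)]
    mapping = {f"m{i:03d}": f"H{i:03d}" for i in range(400)}
    planted = ["H000", "H001", "H002", "H003"]
    human = set(planted) | set(rng.choice(universe[10:], 16, replace=False))
    mouse = {f"m{g[1:]}" for g in planted} | {
        f"m{g[1:]}" for g in rng.choice(universe[200:], 14, replace=False)
    }
    shared, p = ortholog_overlap(human, mouse, mapping, universe, method="empirical",
                                 n=100_000, seed=8)
    assert set(planted) <= set(shared)
    assert p < 0.01


# ---------------------------------------------------------------------------
# tissue-expression similarity null


def test_similarity_null_identical_rows_at_floor():
    rng = np.random.default_rng(60)
    base = rng.normal(size=20)
    rows = {f"bg{i}": rng.normal(size=20) for i in range(100)}
    rows.update({f"f{i}": base + rng.normal(scale=1e-6, size=20) for i in range(4)})
    expr = pd.DataFrame(rows).T
    observed, p = expression_similarity_null(expr, [f"f{i}" for i in range(4)],
                                             n=999, seed=1)
    assert observed > 0.99
    assert p == pytest.approx(1 / 1000)


def test_similarity_null_background_sets_are_unremarkable():
    rng = np.random.default_rng(61)
    expr = pd.DataFrame(rng.normal(size=(150, 25)),
                        index=[f"g{i}" for i in range(150)])
    focal = [f"g{i}" for i in range(10, 16)]
    _, p = expression_similarity_null(expr, focal, n=999, seed=2)
    assert p > 0.05


def test_similarity_null_single_gene_is_an_error():
    expr = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 5)),
                        index=[f"g{i}" for i in range(10)])
    with pytest.raises(ValueError, match="at least 2"):
        expression_similarity_null(expr, ["g1"], n=10, seed=0)
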