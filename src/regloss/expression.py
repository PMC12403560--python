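"""Differential-expression filtering and resampling enrichment tests.

The DE classifier applies the study filters — |log2FC| strictly greater
than 0.5, at least 100 normalized reads in the negative control, and
BH-adjusted p at most 0.05 — to a table produced by a standard DE tool.

Target enrichment in an up- or down-regulated set is judged against a
resampling null: gene sets of the same size are drawn uniformly without
replacement from the expressed universe, the number of predicted targets
in each draw forms the null distribution, and the observed count is
converted to a two-sided Z-score p-value (the exact hypergeometric p is
reported alongside as a cross-check; the null is hypergeometric, so the
two must agree for large resample counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("regloss")


@dataclass
class DESets:
    """Up/down-regulated gene sets and the expressed-gene universe."""

    condition_id: str
    up: frozenset[str]
    down: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")
        if not (self.up | self.down) <= self.universe:
            raise ValueError("up/down sets must be inside the universe")


def classify_de(
    table: pd.DataFrame,
    lfc_min: float = 0.5,
    reads_min: float = 100.0,
    alpha: float = 0.05,
    condition_id: str = "",
) -> DESets:
    """Apply the DE filters to a (gene_id, control_reads, log2fc, padj) table.

    Down: log2fc < -lfc_min (strict) AND control_reads >= reads_min AND
    padj <= alpha; up symmetric.  The universe is every gene with enough
    control reads and a defined adjusted p (genes dropped by independent
    filtering are not part of the tested transcriptome).
    """
    reads_ok = table["control_reads"] >= reads_min
    tested = reads_ok & table["padj"].notna()
    signif = tested & (table["padj"] <= alpha)
    down = signif & (table["log2fc"] < -lfc_min)
    up = signif & (table["log2fc"] > lfc_min)
    return DESets(
        condition_id=condition_id,
        up=frozenset(table.loc[up, "gene_id"]),
        down=frozenset(table.loc[down, "gene_id"]),
        universe=frozenset(table.loc[tested, "gene_id"]),
    )


@dataclass
class EnrichmentResult:
    """Observed vs resampled-null target count for one DE set."""

    observed: int
    null_mean: float
    null_sd: float
    z: float
    p_two_sided: float
    p_exact: float
    n_resamples: int
    rng_seed: int | None


def resample_enrichment(
    de_set: Iterable[str],
    targets: Iterable[str],
    universe: Iterable[str],
    n: int = 1000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Test whether a DE set contains more predicted targets than chance.

    The null draws ``n`` uniform without-replacement samples of size
    |de_set| from the universe and counts targets in each.  ``z`` and the
    two-sided normal p follow; when the null is degenerate (sd = 0) the
    exact hypergeometric p is used instead.
    """
    universe_sorted = sorted(set(universe))
    de = frozenset(de_set)
    tset = frozenset(targets)
    if not de <= set(universe_sorted):
        raise ValueError("de_set is not contained in the universe")
    if not tset <= set(universe_sorted):
        raise ValueError("targets are not contained in the universe")
    if not de:
        raise ValueError("empty DE set")

    is_target = np.array([g in tset for g in universe_sorted])
    n_universe = len(universe_sorted)
    k = len(de)
    observed = len(de & tset)

    rng = np.random.default_rng(seed)
    null = np.empty(n, dtype=np.int64)
    for i in range(n):
        idx = rng.choice(n_universe, size=k, replace=False)
        null[i] = int(is_target[idx].sum())
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))

    # exact two-sided hypergeometric p on the same 2x2 table
    table = [
        [observed, k - observed],
        [len(tset) - observed, (n_universe - k) - (len(tset) - observed)],
    ]
    _, p_exact = stats.fisher_exact(table, alternative="two-sided")

    if null_sd > 0:
        z = (observed - null_mean) / null_sd
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(p, 1.0)
    else:
        z = 0.0
        p = float(p_exact)
    return EnrichmentResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p_two_sided=p,
        p_exact=float(p_exact),
        n_resamples=n,
        rng_seed=seed,
    )


def overlap_significance(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    method: str = "fisher",
    n: int = 1_000_000,
    seed: int | None = None,
) -> tuple[int, float]:
    """Significance of the overlap between two gene sets.

    ``fisher``: two-sided Fisher exact test on the overlap table.
    ``empirical``: p = (r + 1) / (n + 1) where r counts resamples whose
    overlap with ``set_b`` reaches the observed one when |set_a|-sized
    sets are drawn uniformly from the universe (the overlap count of such
    a draw is hypergeometric, and is sampled directly for speed).
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    a = frozenset(set_a)
    b = frozenset(set_b)
    if not (a <= uni and b <= uni):
        raise ValueError("both sets must be contained in the universe")
    observed = len(a & b)
    if method == "fisher":
        table = [
            [observed, len(a) - observed],
            [len(b) - observed, len(uni) - len(a) - len(b) + observed],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return observed, float(p)
    if method == "empirical":
        rng = np.random.default_rng(seed)
        draws = rng.hypergeometric(len(b), len(uni) - len(b), len(a), size=n)
        r = int((draws >= observed).sum())
        return observed, (r + 1) / (n + 1)
    raise ValueError(f"unknown method {method!r}")


def ortholog_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    ortholog_map: Mapping[str, str],
    universe: Iterable[str],
    method: str = "fisher",
    n: int = 1_000_000,
    seed: int | None = None,
) -> tuple[list[str], float]:
    """Cross-species overlap after mapping set B into set A's namespace.

    ``ortholog_map`` must be 1:1 on the tested universe (B-namespace ->
    A-namespace).  Genes without a mapping are dropped with a logged
    count.  Returns the shared genes (A namespace, sorted) and the p-value
    from :func:`overlap_significance`.
    """
    values = list(ortholog_map.values())
    if len(values) != len(set(values)):
        raise ValueError("ortholog map is not 1:1")
    b_list = list(set_b)
    mapped = {ortholog_map[g] for g in b_list if g in ortholog_map}
    dropped = sum(1 for g in b_list if g not in ortholog_map)
    if dropped:
        logger.warning("ortholog_overlap: dropped %d unmapped genes", dropped)
    uni = frozenset(universe)
    a = frozenset(set_a) & uni
    mapped &= uni
    if not mapped and dropped:
        logger.warning("ortholog_overlap: no genes of set B could be mapped")
    observed, p = overlap_significance(a, mapped, uni, method=method, n=n, seed=seed)
    return sorted(a & mapped), p


def expression_similarity_null(
    expr: pd.DataFrame,
    focal: Iterable[str],
    n: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Are the focal genes' expression vectors more alike than chance?

    Statistic: mean pairwise Pearson r of the focal rows of a genes x
    tissues matrix.  Null: the same statistic for ``n`` uniformly drawn
    same-size gene sets.  One-sided p = (r + 1) / (n + 1) with r the
    number of null statistics at or above the observed one.  Constant
    rows are excluded with a warning (their correlation is undefined).
    """
    focal_ids = list(dict.fromkeys(focal))
    missing = [g for g in focal_ids if g not in expr.index]
    if missing:
        raise ValueError(f"focal genes missing from expression matrix: {missing}")
    constant = expr.std(axis=1) == 0
    if constant.any():
        logger.warning(
            "expression_similarity_null: excluding %d constant rows",
            int(constant.sum()),
        )
        expr = expr.loc[~constant]
        focal_ids = [g for g in focal_ids if g in expr.index]
    if len(focal_ids) < 2:
        raise ValueError("need at least 2 (non-constant) focal genes")

    def mean_pairwise_r(rows: np.ndarray) -> float:
        corr = np.corrcoef(rows)
        iu = np.triu_indices(len(rows), k=1)
        return float(corr[iu].mean())

    matrix = expr.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(expr.index)}
    observed = mean_pairwise_r(matrix[[index[g] for g in focal_ids]])

    rng = np.random.default_rng(seed)
    k = len(focal_ids)
    null = np.empty(n)
    for i in range(n):
        idx = rng.choice(len(expr), size=k, replace=False)
        null[i] = mean_pairwise_r(matrix[idx])
    r = int((null >= observed).sum())
    return observed, (r + 1) / (n + 1)
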