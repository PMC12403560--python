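"""Phylogenetic profiles: binarization, correlation ranking and co-loss mining.

A phylogenetic profile records, for one gene, in which taxa an ortholog was
detected.  miRNA profiles carry a third state — an ortholog whose seed
sequence diverged from the reference — because such a copy has likely
changed target repertoire and is treated as functionally absent by default.

Co-loss mining asks which protein-coding genes disappeared from the same
lineages as a set of focal miRNA families: each gene's binary profile is
correlated (Pearson, equivalently the phi coefficient) against each miRNA
profile, the top percentile per miRNA is kept, and genes similar to at
least a given fraction of the miRNAs are reported as sharing an
evolutionary history with them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .parsimony import dollo_gain_losses
from .trees import SpeciesTree

# ternary cell states of a ProfileMatrix
ABSENT = 0
PRESENT_DIVERGENT_SEED = 1
PRESENT_CONSERVED_SEED = 2  # also plain "present" for protein-coding genes


@dataclass
class ProfileMatrix:
    """Genes x taxa ternary presence/absence matrix.

    ``data`` holds int8 codes (0 absent, 1 present with divergent seed,
    2 present with conserved seed / plain present); rows are genes, columns
    taxa.  The taxon order is fixed at construction and shared by every
    matrix of a run.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        bad = ~self.data.isin([ABSENT, PRESENT_DIVERGENT_SEED, PRESENT_CONSERVED_SEED])
        if bad.to_numpy().any():
            raise ValueError("profile cells must be in {0, 1, 2}")
        self.data = self.data.astype("int8")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @classmethod
    def from_ortholog_table(
        cls, table: pd.DataFrame, taxa: Sequence[str], genes: Sequence[str] | None = None
    ) -> "ProfileMatrix":
        """Densify a sparse long-format ortholog table onto a fixed taxon order.

        Rows absent from the table default to "absent".  A present ortholog
        with ``seed_conserved`` false becomes the divergent-seed state; a
        present ortholog without seed information (protein-coding genes)
        is plain present.
        """
        if genes is None:
            genes = list(dict.fromkeys(table["gene_id"]))
        mat = pd.DataFrame(ABSENT, index=list(genes), columns=list(taxa), dtype="int8")
        has_seed = "seed_conserved" in table.columns
        for row in table.itertuples(index=False):
            if not bool(row.present):
                continue
            state = PRESENT_CONSERVED_SEED
            if has_seed and row.seed_conserved is not None and not pd.isna(
                row.seed_conserved
            ):
                state = (
                    PRESENT_CONSERVED_SEED
                    if bool(row.seed_conserved)
                    else PRESENT_DIVERGENT_SEED
                )
            if row.gene_id not in mat.index or row.taxon_id not in mat.columns:
                continue
            mat.at[row.gene_id, row.taxon_id] = state
        return cls(mat)


def binarize(matrix: ProfileMatrix, divergent_as_absent: bool = True) -> pd.DataFrame:
    """Collapse the ternary profile matrix to 0/1 vectors.

    A conserved-seed (or plain) presence maps to 1; a divergent-seed
    ortholog counts as absent by default because its regulatory function
    has likely changed.
    """
    data = matrix.data
    if divergent_as_absent:
        binary = (data == PRESENT_CONSERVED_SEED).astype("int8")
    else:
        binary = (data != ABSENT).astype("int8")
    return binary


def pearson_binary(u: Sequence[int], v: Sequence[int]) -> float | None:
    """Pearson correlation of two binary vectors (the phi coefficient).

    Returns ``None`` (undefined, not a number) when either vector is
    constant, since phi has a zero denominator there.
    """
    ua = np.asarray(u, dtype=float)
    va = np.asarray(v, dtype=float)
    if ua.shape != va.shape:
        raise ValueError(f"length mismatch: {ua.shape} vs {va.shape}")
    if ua.size < 2:
        raise ValueError("vectors must have length >= 2")
    if np.all(ua == ua[0]) or np.all(va == va[0]):
        return None
    return float(np.corrcoef(ua, va)[0, 1])


def profile_correlations(genes: pd.DataFrame, mirna: pd.Series) -> pd.Series:
    """Pearson r of every gene profile against one miRNA profile (vectorised).

    Constant gene profiles get NaN (undefined, excluded from ranking);
    raises if the miRNA profile itself is constant.
    """
    X = genes.to_numpy(dtype=float)
    y = mirna.to_numpy(dtype=float)
    if X.shape[1] != y.size:
        raise ValueError("taxon order mismatch between genes and miRNA profile")
    if np.all(y == y[0]):
        raise ValueError("miRNA profile is constant; correlation undefined")
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xnorm = np.sqrt((Xc**2).sum(axis=1))
    ynorm = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (xnorm * ynorm)
    r[xnorm == 0] = np.nan
    return pd.Series(r, index=genes.index, name=getattr(mirna, "name", None))


def rank_and_cut(
    genes: pd.DataFrame, mirna: pd.Series, percentile: float = 1.0
) -> set[str]:
    """Genes in the top ``percentile`` percent by Pearson r to the miRNA profile.

    Constant-profile genes are excluded before ranking; all genes tied at
    the cutoff r are included, so the result may exceed the nominal count.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    r = profile_correlations(genes, mirna).dropna()
    if r.empty:
        raise ValueError("no rankable profiles (all gene profiles constant)")
    k = max(1, math.ceil(len(r) * percentile / 100.0))
    cutoff = np.sort(r.to_numpy())[::-1][k - 1]
    return set(r.index[r.to_numpy() >= cutoff])


def mine_coloss(
    genes: pd.DataFrame,
    mirnas: pd.DataFrame,
    percentile: float = 1.0,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Mine genes co-lost with a set of miRNA profiles.

    A gene is reported when it falls into the per-miRNA top-percentile cut
    for at least ``ceil(min_fraction * m)`` of the ``m`` miRNA profiles
    ("at least half" with an odd count rounds up: 8 of 15).  Returns a
    table of the reported genes with their support counts, sorted by
    decreasing support then gene id.
    """
    if mirnas.empty:
        raise ValueError("empty miRNA profile set")
    constant = mirnas.nunique(axis=1) == 1
    usable = mirnas.loc[~constant]
    if usable.empty:
        raise ValueError("all miRNA profiles are constant; nothing to mine")
    m = len(usable)
    need = math.ceil(min_fraction * m)
    support: dict[str, int] = {}
    for _, mirna in usable.iterrows():
        for gene in rank_and_cut(genes, mirna, percentile=percentile):
            support[gene] = support.get(gene, 0) + 1
    hits = [(g, c) for g, c in support.items() if c >= need]
    hits.sort(key=lambda gc: (-gc[1], gc[0]))
    return pd.DataFrame(hits, columns=["gene_id", "n_supporting_mirnas"]).assign(
        n_mirnas=m, min_support=need
    )


@dataclass
class LossReport:
    """Dollo gain/loss placement of one gene on the species tree."""

    gene_id: str
    gain_branch: str
    loss_branches: tuple[str, ...]
    n_independent_losses: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_independent_losses = len(self.loss_branches)


def dollo_loss_report(
    profile: Mapping[str, int] | pd.Series,
    tree: SpeciesTree,
    gene_id: str = "",
) -> LossReport:
    """Characterise where a gene was gained and independently lost.

    Under Dollo parsimony the gain is the edge above the LCA of all taxa
    carrying the gene and each maximal all-absent subtree below it is one
    independent loss.
    """
    if isinstance(profile, pd.Series):
        items = profile.items()
        gene_id = gene_id or str(profile.name or "")
    else:
        items = profile.items()
    present = [taxon for taxon, state in items if state]
    if not present:
        raise ValueError(f"gene {gene_id or '<unnamed>'} never observed in any taxon")
    gain, losses = dollo_gain_losses(tree, present)
    return LossReport(
        gene_id=gene_id,
        gain_branch=gain.branch_id,
        loss_branches=tuple(n.branch_id for n in losses),
    )


def ubiquity_filter(
    binary: pd.DataFrame, threshold: float = 0.95
) -> tuple[set[str], set[str]]:
    """Split genes into (ubiquitous, lineage-lost) by presence fraction.

    A gene is ubiquitous when present in strictly more than ``threshold``
    of the taxa; everything else — including never-observed genes — is
    lineage-lost.
    """
    frac = binary.mean(axis=1)
    ubiquitous = set(frac.index[frac > threshold])
    lost = set(frac.index) - ubiquitous
    return ubiquitous, lost


@dataclass
class FisherEnrichment:
    fold: float
    odds_ratio: float
    p: float


def fisher_enrichment(
    hits_in_set: int, set_size: int, hits_in_universe: int, universe_size: int
) -> FisherEnrichment:
    """Fold enrichment and two-sided Fisher exact p for a gene-set overlap.

    The 2x2 table contrasts annotation hits inside vs outside the set; a
    universe without any hits yields fold 0 and p 1 (degenerate table).
    """
    a, s, h, n = hits_in_set, set_size, hits_in_universe, universe_size
    if not (0 <= a <= s <= n and a <= h <= n and h - a <= n - s):
        raise ValueError(
            f"inconsistent counts: hits_in_set={a}, set_size={s}, "
            f"hits_in_universe={h}, universe_size={n}"
        )
    table = [[a, s - a], [h - a, (n - s) - (h - a)]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    fold = 0.0 if h == 0 else (a / s) / (h / n)
    return FisherEnrichment(fold=float(fold), odds_ratio=float(odds), p=float(p))
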