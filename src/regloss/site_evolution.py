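"""Cross-species target-site homology and parsimony dating of site origin.

Seed-match sites are called per species on the ungapped 3'-UTR, projected
into the columns of the orthologous UTR alignment, and sites whose column
intervals overlap (transitively, by at least one column) are treated as one
homologous site — a single evolutionary character whose presence/absence
pattern over taxa is then placed on the species tree by Dollo (default) or
asymmetric Wagner parsimony.  Site types are dated separately: an 8mer
group never merges with a 6mer group even if their columns overlap,
because the two types have very different gain/loss dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .parsimony import dollo_gain_losses, wagner_gain_losses
from .targeting import SeedSite
from .trees import Node, SpeciesTree, TreeError


@dataclass
class AlignedUTRGroup:
    """Orthologous 3'-UTRs of one gene in a common alignment.

    ``aligned`` maps taxon -> aligned sequence (equal lengths, ``-`` gaps).
    Stripping the gaps recovers each species' input UTR exactly; per-taxon
    maps from ungapped position to alignment column are precomputed.
    """

    gene_id: str
    aligned: Mapping[str, str]
    columns: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.aligned.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.gene_id}: aligned sequences have unequal lengths {sorted(lengths)}"
            )
        self.columns = {}
        for taxon, seq in self.aligned.items():
            self.columns[taxon] = [i for i, ch in enumerate(seq) if ch != "-"]

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self.aligned))

    def ungapped(self, taxon: str) -> str:
        return self.aligned[taxon].replace("-", "")

    def to_columns(self, taxon: str, start: int, end: int) -> tuple[int, int]:
        """Map an ungapped half-open interval to alignment columns."""
        cols = self.columns[taxon]
        if not (0 <= start < end <= len(cols)):
            raise ValueError(
                f"{self.gene_id}/{taxon}: site [{start},{end}) outside UTR "
                f"of length {len(cols)}"
            )
        return cols[start], cols[end - 1] + 1


@dataclass(frozen=True)
class ProjectedSite:
    """A seed site lifted into alignment-column coordinates."""

    site: SeedSite
    taxon_id: str
    col_start: int
    col_end: int


def project_sites(
    group: AlignedUTRGroup, sites: Iterable[SeedSite]
) -> list[ProjectedSite]:
    """Project per-taxon sites (ungapped coordinates) into alignment columns.

    Each site keeps its identity; the mapping is strictly monotone per
    taxon because alignment columns preserve sequence order.
    """
    projected = []
    for site in sites:
        taxon = site.taxon_id
        if taxon not in group.aligned:
            raise ValueError(f"site taxon {taxon!r} not in aligned group {group.gene_id}")
        c0, c1 = group.to_columns(taxon, site.start, site.end)
        projected.append(ProjectedSite(site=site, taxon_id=taxon, col_start=c0, col_end=c1))
    projected.sort(key=lambda p: (p.col_start, p.col_end, p.taxon_id))
    return projected


@dataclass
class SiteHomologyGroup:
    """Orthologous seed sites treated as one evolutionary character."""

    group_id: str
    gene_id: str
    mirna_id: str
    site_type: str
    members: tuple[ProjectedSite, ...]
    col_start: int
    col_end: int

    @property
    def presence(self) -> frozenset[str]:
        return frozenset(p.taxon_id for p in self.members)


def build_homology_groups(
    projected: Sequence[ProjectedSite], gene_id: str = ""
) -> list[SiteHomologyGroup]:
    """Cluster projected sites into homology groups by column overlap.

    Groups are the connected components of the "column intervals share at
    least one alignment column" relation, computed separately per site
    type and per miRNA.  Output order (and hence group ids) is
    deterministic: by miRNA, site type, then leftmost column.
    """
    keys = sorted({(p.site.mirna_id, p.site.site_type) for p in projected})
    groups: list[SiteHomologyGroup] = []
    for mirna_id, site_type in keys:
        pool = sorted(
            (
                p
                for p in projected
                if p.site.mirna_id == mirna_id and p.site.site_type == site_type
            ),
            key=lambda p: (p.col_start, p.col_end, p.taxon_id),
        )
        current: list[ProjectedSite] = []
        max_end = -1
        for p in pool:
            if current and p.col_start >= max_end:
                groups.append(_make_group(current, gene_id, mirna_id, site_type))
                current = []
                max_end = -1
            current.append(p)
            max_end = max(max_end, p.col_end)
        if current:
            groups.append(_make_group(current, gene_id, mirna_id, site_type))
    for i, g in enumerate(groups):
        g.group_id = f"{gene_id or 'gene'}:{g.mirna_id}:{g.site_type}:{i:03d}"
    return groups


def _make_group(
    members: list[ProjectedSite], gene_id: str, mirna_id: str, site_type: str
) -> SiteHomologyGroup:
    return SiteHomologyGroup(
        group_id="",
        gene_id=gene_id,
        mirna_id=mirna_id,
        site_type=site_type,
        members=tuple(members),
        col_start=min(p.col_start for p in members),
        col_end=max(p.col_end for p in members),
    )


@dataclass
class GainAssignment:
    """The branch on which parsimony places a site group's origin."""

    gain_branch: str
    method: str
    loss_branches: tuple[str, ...]
    cost: float | None = None
    group_id: str = ""


def date_gain_dollo(
    presence: Iterable[str], tree: SpeciesTree, group_id: str = ""
) -> GainAssignment:
    """Dollo dating: gain above the LCA of carriers, losses below it."""
    gain, losses = dollo_gain_losses(tree, presence)
    return GainAssignment(
        gain_branch=gain.branch_id,
        method="dollo",
        loss_branches=tuple(n.branch_id for n in losses),
        group_id=group_id,
    )


def date_gain_wagner(
    presence: Iterable[str],
    tree: SpeciesTree,
    gain_cost: float = 2.0,
    loss_cost: float = 1.0,
    group_id: str = "",
) -> GainAssignment:
    """Wagner dating: minimum-cost labelling, root-most gain edge reported."""
    gain, losses, cost = wagner_gain_losses(
        tree, presence, gain_cost=gain_cost, loss_cost=loss_cost
    )
    return GainAssignment(
        gain_branch=gain.branch_id,
        method="wagner",
        loss_branches=tuple(n.branch_id for n in losses),
        cost=cost,
        group_id=group_id,
    )


AT_OR_BEFORE_LCA = "at_or_before_LCA"
AFTER_SPLIT_A = "after_split_A_side"
AFTER_SPLIT_B = "after_split_B_side"


def classify_site_age(
    assignment: GainAssignment, split: tuple[str, str], tree: SpeciesTree
) -> str:
    """Relate a gain branch to a two-species split (e.g. human vs mouse).

    A gain on the edge above the split's LCA or higher predates the split;
    otherwise the gain lies inside the lineage of one of the two species.
    """
    taxon_a, taxon_b = split
    lca = tree.lca([taxon_a, taxon_b])
    gain = tree.node(assignment.gain_branch)
    if tree.is_ancestor_or_self(gain, lca):
        return AT_OR_BEFORE_LCA
    side_a = next(c for c in lca.children if taxon_a in c.leaves)
    side_b = next(c for c in lca.children if taxon_b in c.leaves)
    if tree.is_ancestor_or_self(side_a, gain):
        return AFTER_SPLIT_A
    if tree.is_ancestor_or_self(side_b, gain):
        return AFTER_SPLIT_B
    raise TreeError(
        f"gain branch {assignment.gain_branch!r} lies outside the "
        f"{taxon_a}/{taxon_b} split clade"
    )
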