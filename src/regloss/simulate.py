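"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes,
with the true signal recorded alongside so recovery can be scored:

* :func:`simulate_profiles` — presence/absence profiles evolved down a
  species tree under a Dollo process (losses, never regains), with a set
  of focal miRNAs and co-lost protein genes planted on one clade's stem.
  The planted entities carry exactly the clade-absence pattern (no
  background losses), so the ground truth of the mining task is
  unambiguous; background noise lives in the unplanted genes.
* :func:`simulate_utr_evolution` — orthologous UTRs evolved by
  substitutions only (Jukes-Cantor-style: a hit position switches to one
  of the three alternatives uniformly), with a seed-match site written in
  on one planted branch and inherited below it.  Because there are no
  indels the true alignment is the identity alignment, isolating
  dating-algorithm error from alignment error.
* :func:`simulate_de` — differential-expression tables with planted
  down-regulated targets: log-normal control reads, Gaussian log2
  fold-change noise around a planted effect, p-values from the known
  noise model, BH-adjusted.

All generators are pure functions of their configuration and seed: the
same seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import io as rio
from .profiles import (
    ABSENT,
    PRESENT_CONSERVED_SEED,
    PRESENT_DIVERGENT_SEED,
    ProfileMatrix,
)
from .site_evolution import AlignedUTRGroup
from .targeting import (
    MatureMiRNA,
    Seed,
    SeedSite,
    extract_seed,
    scan_utr,
    site_patterns,
)
from .trees import Node, SpeciesTree

#: 10-taxon fixture tree: a glires clade with a Eumuroidea-like murid pair
#: plus hamster, primates, and a carnivore outgroup.
FIXTURE_TREE_10 = (
    "((((((Mouse,Rat),Hamster),Squirrel),Rabbit),"
    "(((Human,Chimp),Macaque),Marmoset)),Dog);"
)

#: stem branch of the murid-like clade in the fixture tree
FIXTURE_PLANTED_CLADE = ("Hamster", "Mouse", "Rat")

_BASES = np.array(list("ACGU"))


@dataclass
class SimConfig:
    """Knobs of the synthetic-data generators (defaults = study conditions)."""

    rng_seed: int = 42
    # profiles
    n_taxa: int = 60
    n_protein_genes: int = 1000
    n_planted_genes: int = 20
    n_mirnas: int = 15
    n_control_mirnas: int = 6
    background_loss_rate: float = 0.02
    planted_clade_size: int = 8
    divergent_seed_rate: float = 0.0
    # UTR evolution
    substitution_rate: float = 0.01
    utr_length: int = 300
    # differential expression
    n_de_genes: int = 1000
    de_effect: float = 2.0
    de_noise_sd: float = 0.25
    reads_median: float = 600.0
    reads_sigma: float = 0.8
    fraction_true_targets: float = 0.05

    def __post_init__(self) -> None:
        for name in ("background_loss_rate", "substitution_rate",
                     "divergent_seed_rate", "fraction_true_targets"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.utr_length <= 0 or self.n_taxa <= 0:
            raise ValueError("lengths and counts must be positive")


@dataclass
class ProfileTruth:
    """Ground truth of one profile simulation."""

    planted_genes: tuple[str, ...]
    planted_mirnas: tuple[str, ...]
    planted_branch: str
    loss_branches: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class SiteTruth:
    """Ground truth of one simulated site-homology group."""

    gene_id: str
    planted_branch: str
    site_type: str
    window_start: int
    window_end: int
    presence: frozenset[str]
    clean: bool


@dataclass
class DETruth:
    """Ground truth of one simulated DE table."""

    true_targets: tuple[str, ...]
    effect: float
    boundary_expectations: dict[str, str] = field(default_factory=dict)


def random_tree(n_taxa: int, rng: np.random.Generator, prefix: str = "t") -> SpeciesTree:
    """A random rooted bifurcating tree by successive random joins."""
    if n_taxa < 3:
        raise ValueError("degenerate tree: need at least 3 taxa")
    labels = [f"{prefix}{i:03d}" for i in range(1, n_taxa + 1)]
    subtrees = list(labels)
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a},{b})")
    return SpeciesTree.from_newick(subtrees[0] + ";")


def _pick_planted_clade(tree: SpeciesTree, size: int) -> Node:
    """Internal non-root node whose leaf count is closest to ``size``."""
    candidates = [
        n for n in tree.preorder() if n.parent is not None and not n.is_leaf
    ]
    if not candidates:
        raise ValueError("tree has no internal non-root node to plant on")
    return min(candidates, key=lambda n: (abs(len(n.leaves) - size), n.branch_id))


def simulate_profiles(
    cfg: SimConfig,
    tree: SpeciesTree | None = None,
    planted_clade: str | None = None,
) -> tuple[ProfileMatrix, ProfileMatrix, SpeciesTree, ProfileTruth]:
    """Simulate protein and miRNA profile matrices with a planted co-loss.

    Every gene is present at the root and is lost along branches with the
    background loss rate (Dollo: no regain).  The planted co-lost genes
    and the focal miRNAs are instead absent exactly in the planted clade;
    control miRNAs are present everywhere, with an optional rate of
    divergent-seed cells.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    if tree is None:
        tree = random_tree(cfg.n_taxa, rng)
    if len(tree) < 3:
        raise ValueError("degenerate tree: need at least 3 taxa")
    planted = (
        tree.node(planted_clade)
        if planted_clade is not None
        else _pick_planted_clade(tree, cfg.planted_clade_size)
    )

    taxa = list(tree.taxa)
    n_bg = cfg.n_protein_genes - cfg.n_planted_genes
    if n_bg < 0:
        raise ValueError("more planted genes than genes")
    planted_genes = [f"g{i:04d}" for i in range(1, cfg.n_planted_genes + 1)]
    bg_genes = [
        f"g{i:04d}" for i in range(cfg.n_planted_genes + 1, cfg.n_protein_genes + 1)
    ]

    # background Dollo process, vectorised over genes
    present = {tree.root: np.ones(n_bg, dtype=bool)}
    loss_record: dict[str, list[str]] = {g: [] for g in bg_genes}
    for node in tree.preorder():
        if node is tree.root:
            continue
        par = present[node.parent]
        if node is planted:
            # background losses never hit the planted stem itself, so the
            # planted clade-absence pattern stays unique to the planted
            # genes and the mining ground truth is identifiable
            present[node] = par
            continue
        lost_here = par & (rng.random(n_bg) < cfg.background_loss_rate)
        present[node] = par & ~lost_here
        for gi in np.nonzero(lost_here)[0]:
            loss_record[bg_genes[gi]].append(node.branch_id)

    planted_leafset = planted.leaves
    gene_rows = {}
    for g in planted_genes:
        gene_rows[g] = [
            ABSENT if t in planted_leafset else PRESENT_CONSERVED_SEED for t in taxa
        ]
        loss_record[g] = [planted.branch_id]
    for gi, g in enumerate(bg_genes):
        states = []
        for t in taxa:
            leaf = tree.leaf(t)
            states.append(
                PRESENT_CONSERVED_SEED if present[leaf][gi] else ABSENT
            )
        gene_rows[g] = states
    genes_pm = ProfileMatrix(
        pd.DataFrame.from_dict(gene_rows, orient="index", columns=taxa)
    )

    focal = [f"mir{i:02d}" for i in range(1, cfg.n_mirnas + 1)]
    control = [f"mirC{i:02d}" for i in range(1, cfg.n_control_mirnas + 1)]
    mirna_rows = {}
    for m in focal:
        mirna_rows[m] = [
            ABSENT if t in planted_leafset else PRESENT_CONSERVED_SEED for t in taxa
        ]
        loss_record[m] = [planted.branch_id]
    for m in control:
        states = np.full(len(taxa), PRESENT_CONSERVED_SEED, dtype=int)
        if cfg.divergent_seed_rate > 0:
            div = rng.random(len(taxa)) < cfg.divergent_seed_rate
            states[div] = PRESENT_DIVERGENT_SEED
        mirna_rows[m] = states.tolist()
    mirnas_pm = ProfileMatrix(
        pd.DataFrame.from_dict(mirna_rows, orient="index", columns=taxa)
    )

    truth = ProfileTruth(
        planted_genes=tuple(planted_genes),
        planted_mirnas=tuple(focal),
        planted_branch=planted.branch_id,
        loss_branches={g: tuple(b) for g, b in loss_record.items()},
    )
    return genes_pm, mirnas_pm, tree, truth


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitution-only evolution along one branch (uniform among the
    three alternative bases)."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGU" if b != out[i]]
        out[i] = alternatives[rng.integers(0, 3)]
    return out


def simulate_utr_evolution(
    cfg: SimConfig,
    tree: SpeciesTree,
    seed: Seed,
    planted_gain_branch: str,
    rng: np.random.Generator,
    site_type: str = "8mer",
    gene_id: str = "utrg001",
) -> tuple[AlignedUTRGroup, SiteTruth]:
    """Evolve one orthologous UTR group with a planted seed-site gain.

    The site pattern is written into the sequence on the planted branch
    (after that branch's substitutions) and inherited below; substitutions
    on descendant branches may erode it.  The truth records, by re-scanning
    every leaf, which taxa still carry a site of the planted type
    overlapping the planted window, and whether the character history is
    clean (present exactly in the planted clade, no convergent gains at
    the locus).
    """
    pattern = site_patterns(seed)[site_type]
    if len(pattern) > cfg.utr_length:
        raise ValueError("site pattern longer than the UTR")
    planted_node = tree.node(planted_gain_branch)
    L = cfg.utr_length
    pos = int(rng.integers(0, L - len(pattern) + 1))
    pat_arr = np.array(list(pattern))

    root_seq = _BASES[rng.integers(0, 4, size=L)]
    if planted_node is tree.root:
        root_seq[pos : pos + len(pattern)] = pat_arr
    seqs = {tree.root: root_seq}
    for node in tree.preorder():
        if node is tree.root:
            continue
        child_seq = _mutate(seqs[node.parent], cfg.substitution_rate, rng)
        if node is planted_node:
            child_seq[pos : pos + len(pattern)] = pat_arr
        seqs[node] = child_seq

    aligned = {
        leaf: "".join(seqs[tree.leaf(leaf)]) for leaf in tree.taxa
    }
    group = AlignedUTRGroup(gene_id=gene_id, aligned=aligned)

    window = (pos, pos + len(pattern))
    presence = set()
    for taxon, utr in aligned.items():
        for site in scan_utr(utr, seed):
            if site.site_type == site_type and site.start < window[1] and site.end > window[0]:
                presence.add(taxon)
                break
    clean = frozenset(presence) == planted_node.leaves
    return group, SiteTruth(
        gene_id=gene_id,
        planted_branch=planted_gain_branch,
        site_type=site_type,
        window_start=window[0],
        window_end=window[1],
        presence=frozenset(presence),
        clean=clean,
    )


def simulate_dating_cohort(
    cfg: SimConfig,
    tree: SpeciesTree,
    seed: Seed,
    n_groups: int,
    rng: np.random.Generator | None = None,
    site_type: str = "8mer",
) -> list[tuple[AlignedUTRGroup, SiteTruth]]:
    """A cohort of independent UTR groups with gains planted on random branches."""
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    branch_ids = [n.branch_id for n in tree.preorder()]
    cohort = []
    for i in range(n_groups):
        branch = branch_ids[int(rng.integers(0, len(branch_ids)))]
        group, truth = simulate_utr_evolution(
            cfg,
            tree,
            seed,
            branch,
            rng,
            site_type=site_type,
            gene_id=f"utrg{i + 1:03d}",
        )
        cohort.append((group, truth))
    return cohort


def evaluate_dating_recovery(
    cohort: list[tuple[AlignedUTRGroup, SiteTruth]],
    tree: SpeciesTree,
    seed: Seed,
) -> dict:
    """Score gain-branch recovery of a simulated dating cohort.

    Runs the actual analysis path on each group — scan every leaf UTR,
    project into alignment columns, build homology groups, date the group
    of the planted type overlapping the planted window with Dollo — and
    compares the dated branch to the planted one.  Groups whose site was
    eroded in every leaf cannot be dated and are excluded from the
    denominators; ``clean`` groups (present exactly in the planted clade,
    no convergent gains at the locus) are always dateable.
    """
    from .site_evolution import build_homology_groups, date_gain_dollo, project_sites
    from .targeting import scan_utr as _scan

    n_dateable = n_recovered = n_clean = n_clean_recovered = 0
    for group, truth in cohort:
        sites = []
        for taxon in group.taxa:
            for site in _scan(group.ungapped(taxon), seed):
                sites.append(
                    SeedSite(
                        start=site.start, end=site.end, site_type=site.site_type,
                        mirna_id=site.mirna_id, gene_id=group.gene_id,
                        taxon_id=taxon,
                    )
                )
        projected = project_sites(group, sites)
        target = None
        for hg in build_homology_groups(projected, gene_id=group.gene_id):
            if (hg.site_type == truth.site_type
                    and hg.col_start < truth.window_end
                    and hg.col_end > truth.window_start):
                target = hg
                break
        if target is None:
            continue
        n_dateable += 1
        assignment = date_gain_dollo(sorted(target.presence), tree)
        recovered = assignment.gain_branch == truth.planted_branch
        n_recovered += recovered
        if truth.clean:
            n_clean += 1
            n_clean_recovered += recovered
    return {
        "n_groups": len(cohort),
        "n_dateable": n_dateable,
        "n_clean": n_clean,
        "clean_recovery": (n_clean_recovered / n_clean) if n_clean else float("nan"),
        "overall_recovery": (n_recovered / n_dateable) if n_dateable else float("nan"),
    }


_BOUNDARY_ROWS = [
    # gene_id, control_reads, log2fc, padj, expectation
    ("boundary_lfc_at_min", 500.0, 0.5, 0.01, "excluded: |log2fc| not > 0.5"),
    ("boundary_padj_at_alpha", 500.0, -1.0, 0.05, "down: padj <= 0.05 inclusive"),
    ("boundary_reads_low", 99.0, -2.0, 0.001, "excluded: < 100 control reads"),
]


def simulate_de(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    true_targets: list[str] | None = None,
    gene_ids: list[str] | None = None,
    include_boundary_cases: bool = False,
) -> tuple[pd.DataFrame, DETruth]:
    """Simulate a DE result table with planted down-regulated targets.

    True targets receive log2fc = -effect plus Gaussian noise; all other
    genes are centred at zero.  p-values come from the known noise model
    (two-sided normal) and are BH-adjusted.  Optionally three sentinel
    records probing the classifier's filter boundaries are appended with
    literal values (their padj is set directly, not via BH).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    if gene_ids is None:
        gene_ids = [f"deg{i:04d}" for i in range(1, cfg.n_de_genes + 1)]
    n = len(gene_ids)
    if true_targets is None:
        k = int(round(cfg.fraction_true_targets * n))
        idx = rng.choice(n, size=k, replace=False)
        true_targets = [gene_ids[i] for i in sorted(idx)]
    target_mask = np.isin(gene_ids, true_targets)

    control_reads = rng.lognormal(
        mean=np.log(cfg.reads_median), sigma=cfg.reads_sigma, size=n
    )
    lfc = rng.normal(0.0, cfg.de_noise_sd, size=n)
    lfc[target_mask] -= cfg.de_effect
    pvals = 2.0 * stats.norm.sf(np.abs(lfc) / cfg.de_noise_sd)
    padj = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "control_reads": np.round(control_reads, 3),
            "log2fc": np.round(lfc, 4),
            "padj": padj,
        }
    )
    boundary: dict[str, str] = {}
    if include_boundary_cases:
        extra = pd.DataFrame(
            [(g, r, f, p) for g, r, f, p, _ in _BOUNDARY_ROWS],
            columns=["gene_id", "control_reads", "log2fc", "padj"],
        )
        table = pd.concat([table, extra], ignore_index=True)
        boundary = {g: note for g, _, _, _, note in _BOUNDARY_ROWS}
    truth = DETruth(
        true_targets=tuple(true_targets),
        effect=cfg.de_effect,
        boundary_expectations=boundary,
    )
    return table, truth


def _random_mature(rng: np.random.Generator, length: int = 22) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_fixture(name: str, out_dir, seed: int = 42) -> dict:
    """Write a complete, versioned synthetic input bundle to ``out_dir``.

    ``mini`` is sized to run the whole pipeline end to end in well under a
    minute; ``standard`` matches the generator's default study conditions.
    Returns a small metadata dictionary (paths and key ids).
    """
    presets = {
        "mini": dict(
            n_protein_genes=120, n_planted_genes=8, n_mirnas=5, n_control_mirnas=2,
            n_de_genes=200, utr_length=200, n_groups=12,
        ),
        "standard": dict(
            n_protein_genes=1000, n_planted_genes=20, n_mirnas=15,
            n_control_mirnas=6, n_de_genes=1000, utr_length=300, n_groups=200,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r} (choose mini or standard)")
    p = presets[name]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    if name == "mini":
        tree = SpeciesTree.from_newick(FIXTURE_TREE_10)
        planted_clade = "+".join(FIXTURE_PLANTED_CLADE)
    else:
        tree = random_tree(60, rng)
        planted_clade = None

    cfg = SimConfig(
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        n_taxa=len(tree),
        n_protein_genes=p["n_protein_genes"],
        n_planted_genes=p["n_planted_genes"],
        n_mirnas=p["n_mirnas"],
        n_control_mirnas=p["n_control_mirnas"],
        n_de_genes=p["n_de_genes"],
        utr_length=p["utr_length"],
        divergent_seed_rate=0.05,
    )
    genes_pm, mirnas_pm, tree, prof_truth = simulate_profiles(
        cfg, tree=tree, planted_clade=planted_clade
    )

    # mature sequences: focal miRNAs (profile ids) + an unrelated extant set
    focal_ids = list(prof_truth.planted_mirnas)
    matures = [MatureMiRNA(m, _random_mature(rng)) for m in focal_ids]
    extant = [MatureMiRNA(f"extR{i:02d}", _random_mature(rng)) for i in range(1, 6)]

    # orthologous UTRs with sites of the first focal miRNA planted
    seed7 = extract_seed(matures[0])
    cohort = simulate_dating_cohort(
        cfg, tree, seed7, p["n_groups"], rng=rng, site_type="8mer"
    )

    # site scores + DE table: a subset of expressed genes are predicted
    # targets of the first focal miRNA; most of those get a planted effect
    de_genes = [f"deg{i:04d}" for i in range(1, cfg.n_de_genes + 1)]
    n_pred = max(10, cfg.n_de_genes // 7)
    pred_idx = sorted(rng.choice(cfg.n_de_genes, size=n_pred, replace=False))
    predicted = [de_genes[i] for i in pred_idx]
    n_true = max(5, int(0.75 * n_pred))
    true_targets = predicted[:n_true]
    score_rows = []
    for g in predicted:
        n_sites = int(rng.integers(1, 3))
        for s in range(n_sites):
            start = int(rng.integers(0, 150))
            score_rows.append(
                (g, focal_ids[0], start, start + 8, "8mer",
                 round(-(0.2 / n_sites) - 0.2 * rng.random(), 4))
            )
    n_weak = n_pred // 2
    weak_idx = sorted(rng.choice(cfg.n_de_genes, size=n_weak, replace=False))
    for i in weak_idx:
        g = de_genes[i]
        if g in predicted:
            continue
        start = int(rng.integers(0, 150))
        score_rows.append(
            (g, focal_ids[0], start, start + 6, "6mer",
             round(-0.05 * rng.random(), 4))
        )
    site_scores = pd.DataFrame(
        score_rows,
        columns=["gene_id", "mirna_id", "site_start", "site_end", "site_type",
                 "context_score"],
    ).sort_values(["gene_id", "mirna_id", "site_start"]).reset_index(drop=True)

    de_table, de_truth = simulate_de(
        cfg, rng=rng, true_targets=true_targets, gene_ids=de_genes,
        include_boundary_cases=True,
    )

    # ---- write the bundle -------------------------------------------------
    tree.write(out / "tree.nwk")

    def long_format(pm: ProfileMatrix, with_seed: bool) -> pd.DataFrame:
        rows = []
        for g in pm.genes:
            for t in pm.taxa:
                state = int(pm.data.at[g, t])
                if state == ABSENT:
                    continue
                if with_seed:
                    rows.append((g, t, 1, int(state == PRESENT_CONSERVED_SEED)))
                else:
                    rows.append((g, t, 1))
        cols = ["gene_id", "taxon_id", "present"] + (
            ["seed_conserved"] if with_seed else []
        )
        return pd.DataFrame(rows, columns=cols)

    utr_groups = {g.gene_id: dict(g.aligned) for g, _ in cohort}

    rio.write_utr_fasta(utr_groups, out / "utrs_aln.fasta")
    rio.write_utr_fasta(utr_groups, out / "utrs.fasta")  # identity alignment
    with open(out / "mature_mirnas.fasta", "w") as fh:
        for m in matures:
            fh.write(f">{m.mirna_id}\n{m.sequence}\n")
    with open(out / "extant_mirnas.fasta", "w") as fh:
        for m in extant:
            fh.write(f">{m.mirna_id}\n{m.sequence}\n")

    truth_sites = pd.DataFrame(
        [
            (t.gene_id, t.planted_branch, t.site_type, t.window_start,
             t.window_end, ",".join(sorted(t.presence)), int(t.clean))
            for _, t in cohort
        ],
        columns=["gene_id", "planted_branch", "site_type", "window_start",
                 "window_end", "presence", "clean"],
    )
    truth_coloss = pd.DataFrame(
        {"gene_id": list(prof_truth.planted_genes),
         "planted_branch": prof_truth.planted_branch}
    )
    truth_de = pd.DataFrame({"gene_id": list(de_truth.true_targets),
                             "log2fc_effect": -de_truth.effect})

    tables = {
        "protein_orthologs": long_format(genes_pm, with_seed=False),
        "mirna_orthologs": long_format(mirnas_pm, with_seed=True),
        "site_scores": site_scores,
        "de": de_table,
        "truth_coloss": truth_coloss,
        "truth_sites": truth_sites,
        "truth_de": truth_de,
    }
    rio.write_results(
        tables, out, seed=seed,
        config={"preset": name, **{k: getattr(cfg, k) for k in vars(cfg)}},
    )
    return {
        "out_dir": str(out),
        "preset": name,
        "planted_branch": prof_truth.planted_branch,
        "focal_mirnas": focal_ids,
        "planted_genes": list(prof_truth.planted_genes),
        "true_de_targets": list(de_truth.true_targets),
    }
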