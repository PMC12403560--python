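"""The four analysis stages as plain functions over files.

Each stage reads its inputs through :mod:`regloss.io`, calls the library,
and writes TSV results plus a manifest with :func:`regloss.io.write_results`
so that identical inputs and seed give byte-identical output.  The CLI in
:mod:`regloss.cli` is a thin wrapper around these functions; they are
equally usable from Python (the test-suite and the acceptance script call
them directly).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io as rio
from .expression import classify_de, resample_enrichment
from .profiles import ProfileMatrix, binarize, dollo_loss_report, mine_coloss
from .simulate import make_fixture
from .site_evolution import (
    build_homology_groups,
    classify_site_age,
    date_gain_dollo,
    date_gain_wagner,
    project_sites,
)
from .targeting import (
    SeedSite,
    aggregate_tc_table,
    compensation_scan,
    extract_seed,
    scan_utr,
)


def run_simulate(preset: str, out_dir, seed: int = 42) -> dict:
    """Stage 0: write a synthetic input bundle with ground truth."""
    return make_fixture(preset, out_dir, seed=seed)


def run_profiles(
    orthologs_path,
    mirnas_path,
    tree_path,
    out_dir,
    percentile: float = 1.0,
    min_fraction: float = 0.5,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Stage 1: co-loss mining and loss-branch characterisation."""
    tree = rio.read_newick(tree_path)
    taxa = list(tree.taxa)
    genes_pm = ProfileMatrix.from_ortholog_table(
        rio.read_ortholog_table(orthologs_path), taxa
    )
    mirnas_pm = ProfileMatrix.from_ortholog_table(
        rio.read_ortholog_table(mirnas_path), taxa
    )
    genes_bin = binarize(genes_pm)
    # the focal set are families genuinely missing somewhere: a merely
    # seed-divergent ortholog marks functional change, not family loss
    lost_mask = (mirnas_pm.data == 0).any(axis=1)
    mirnas_bin = binarize(mirnas_pm).loc[lost_mask]
    if mirnas_bin.empty:
        raise ValueError("no lineage-lost miRNA families in the input table")

    coloss = mine_coloss(
        genes_bin, mirnas_bin, percentile=percentile, min_fraction=min_fraction
    )

    reports = []
    for mirna_id, profile in mirnas_bin.iterrows():
        if profile.sum() == 0:
            continue
        rep = dollo_loss_report(profile, tree, gene_id=str(mirna_id))
        reports.append(
            (rep.gene_id, rep.gain_branch, ";".join(rep.loss_branches),
             rep.n_independent_losses)
        )
    loss_report = pd.DataFrame(
        reports,
        columns=["gene_id", "gain_branch", "loss_branches", "n_independent_losses"],
    )

    from .profiles import profile_correlations

    corr_cols = {}
    for mirna_id, profile in mirnas_bin.iterrows():
        if profile.nunique() == 1:
            continue
        corr_cols[str(mirna_id)] = profile_correlations(genes_bin, profile).round(6)
    correlations = pd.DataFrame(corr_cols)
    correlations.insert(0, "gene_id", correlations.index)
    correlations = correlations.reset_index(drop=True)

    tables = {
        "coloss_genes": coloss,
        "loss_report": loss_report,
        "correlation_matrix": correlations,
    }
    rio.write_results(
        tables, out_dir, seed=seed,
        config={"stage": "profiles", "percentile": percentile,
                "min_fraction": min_fraction},
    )
    return tables


def run_targets(
    mirnas_path,
    utrs_path,
    out_dir,
    site_scores_path=None,
    extant_path=None,
    tc_threshold: float = -0.2,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Stage 2: seed-site scanning, target calling, compensation scan."""
    matures = rio.read_mirna_fasta(mirnas_path)
    utrs = rio.read_utr_fasta(utrs_path, aligned=False)

    rows = []
    for mature in matures:
        seed7 = extract_seed(mature)
        for gene_id in sorted(utrs):
            for taxon_id in sorted(utrs[gene_id]):
                for site in scan_utr(utrs[gene_id][taxon_id], seed7):
                    rows.append(
                        (gene_id, taxon_id, mature.mirna_id, site.start,
                         site.end, site.site_type)
                    )
    sites = pd.DataFrame(
        rows,
        columns=["gene_id", "taxon_id", "mirna_id", "site_start", "site_end",
                 "site_type"],
    )

    tables: dict[str, pd.DataFrame] = {"sites": sites}
    if site_scores_path is not None:
        scores = rio.read_site_scores(site_scores_path)
        tables["targets"] = aggregate_tc_table(scores, threshold=tc_threshold)
    if extant_path is not None:
        extant = rio.read_mirna_fasta(extant_path)
        comp_seed = compensation_scan(matures, extant, mode="seed_exact")
        comp_short = compensation_scan(matures, extant, mode="short_match")
        tables["compensation"] = pd.concat(
            [comp_seed, comp_short], ignore_index=True
        )
    rio.write_results(
        tables, out_dir, seed=seed,
        config={"stage": "targets", "tc_threshold": tc_threshold},
    )
    return tables


def run_dates(
    alignments_path,
    sites_path,
    tree_path,
    out_dir,
    method: str = "dollo",
    split: tuple[str, str] | None = None,
    gain_cost: float = 2.0,
    loss_cost: float = 1.0,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Stage 3: site homology grouping and parsimony dating of origins."""
    if method not in ("dollo", "wagner"):
        raise ValueError(f"unknown dating method {method!r}")
    tree = rio.read_newick(tree_path)
    groups_fa = rio.read_utr_fasta(alignments_path, aligned=True)
    sites_df = pd.read_csv(sites_path, sep="\t", dtype={
        "gene_id": str, "taxon_id": str, "mirna_id": str, "site_type": str})

    from .site_evolution import AlignedUTRGroup

    group_rows = []
    gain_rows = []
    for gene_id in sorted(groups_fa):
        aln = AlignedUTRGroup(gene_id=gene_id, aligned=groups_fa[gene_id])
        gene_sites = sites_df[sites_df["gene_id"] == gene_id]
        seed_sites = [
            SeedSite(
                start=int(r.site_start), end=int(r.site_end),
                site_type=r.site_type, mirna_id=r.mirna_id,
                gene_id=gene_id, taxon_id=r.taxon_id,
            )
            for r in gene_sites.itertuples(index=False)
        ]
        projected = project_sites(aln, seed_sites)
        for hg in build_homology_groups(projected, gene_id=gene_id):
            presence = sorted(hg.presence)
            if method == "dollo":
                assignment = date_gain_dollo(presence, tree, group_id=hg.group_id)
            else:
                assignment = date_gain_wagner(
                    presence, tree, gain_cost=gain_cost, loss_cost=loss_cost,
                    group_id=hg.group_id,
                )
            age = ""
            if split is not None:
                try:
                    age = classify_site_age(assignment, split, tree)
                except Exception:
                    age = "outside_split_clade"
            group_rows.append(
                (hg.group_id, gene_id, hg.mirna_id, hg.site_type,
                 hg.col_start, hg.col_end, len(hg.members),
                 ",".join(presence))
            )
            gain_rows.append(
                (hg.group_id, gene_id, hg.mirna_id, hg.site_type,
                 assignment.gain_branch, ";".join(assignment.loss_branches),
                 method, age)
            )
    site_groups = pd.DataFrame(
        group_rows,
        columns=["group_id", "gene_id", "mirna_id", "site_type", "col_start",
                 "col_end", "n_members", "presence"],
    )
    gains = pd.DataFrame(
        gain_rows,
        columns=["group_id", "gene_id", "mirna_id", "site_type", "gain_branch",
                 "loss_branches", "method", "age_class"],
    )
    branch_counts = (
        gains.groupby(["gain_branch", "site_type"], sort=True)
        .size()
        .reset_index(name="n_gains")
    )
    tables = {
        "site_groups": site_groups,
        "gain_assignments": gains,
        "branch_gain_counts": branch_counts,
    }
    rio.write_results(
        tables, out_dir, seed=seed,
        config={"stage": "dates", "method": method, "split": split,
                "gain_cost": gain_cost, "loss_cost": loss_cost},
    )
    return tables


def run_enrich(
    de_path,
    targets_path,
    out_dir,
    n: int = 1000,
    seed: int = 0,
    lfc_min: float = 0.5,
    reads_min: float = 100.0,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Stage 4: DE classification and resampling target enrichment."""
    de_table = rio.read_de_table(de_path)
    targets_df = pd.read_csv(targets_path, sep="\t", dtype={
        "gene_id": str, "mirna_id": str})
    sets = classify_de(de_table, lfc_min=lfc_min, reads_min=reads_min, alpha=alpha)

    de_sets = pd.DataFrame(
        [("down", g) for g in sorted(sets.down)]
        + [("up", g) for g in sorted(sets.up)],
        columns=["direction", "gene_id"],
    )

    enrich_rows = []
    for mirna_id, sub in targets_df.groupby("mirna_id", sort=True):
        predicted = frozenset(
            sub.loc[sub["is_predicted_target"].astype(bool), "gene_id"]
        ) & sets.universe
        for direction, de_set in (("down", sets.down), ("up", sets.up)):
            if not de_set:
                continue
            res = resample_enrichment(
                de_set, predicted, sets.universe, n=n, seed=seed
            )
            enrich_rows.append(
                (mirna_id, direction, len(de_set), len(predicted), res.observed,
                 round(res.null_mean, 4), round(res.null_sd, 4),
                 round(res.z, 4), res.p_two_sided, res.p_exact, res.n_resamples)
            )
    enrichment = pd.DataFrame(
        enrich_rows,
        columns=["mirna_id", "direction", "n_de", "n_targets", "observed",
                 "null_mean", "null_sd", "z", "p_two_sided", "p_exact",
                 "n_resamples"],
    )
    tables = {"de_sets": de_sets, "enrichment": enrichment}
    rio.write_results(
        tables, out_dir, seed=seed,
        config={"stage": "enrich", "n": n, "lfc_min": lfc_min,
                "reads_min": reads_min, "alpha": alpha},
    )
    return tables


def run_all(bundle_dir, out_dir, seed: int = 0) -> dict[str, Path]:
    """Run all four stages on a simulated bundle; returns stage out dirs."""
    bundle = Path(bundle_dir)
    out = Path(out_dir)
    stage_dirs = {name: out / name for name in
                  ("profiles", "targets", "dates", "enrich")}
    run_profiles(
        bundle / "protein_orthologs.tsv", bundle / "mirna_orthologs.tsv",
        bundle / "tree.nwk", stage_dirs["profiles"], seed=seed,
    )
    run_targets(
        bundle / "mature_mirnas.fasta", bundle / "utrs.fasta",
        stage_dirs["targets"], site_scores_path=bundle / "site_scores.tsv",
        extant_path=bundle / "extant_mirnas.fasta", seed=seed,
    )
    run_dates(
        bundle / "utrs_aln.fasta", stage_dirs["targets"] / "sites.tsv",
        bundle / "tree.nwk", stage_dirs["dates"], split=("Human", "Mouse"),
        seed=seed,
    )
    run_enrich(
        bundle / "de.tsv", stage_dirs["targets"] / "targets.tsv",
        stage_dirs["enrich"], seed=seed,
    )
    return stage_dirs
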