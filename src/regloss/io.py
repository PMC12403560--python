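"""Readers and writers for every external format the pipeline touches.

All downstream modules operate on in-memory domain objects; this module is
the only place that parses or serialises files.  Conventions:

* coordinates are 0-based, half-open, on the UTR sense strand (5'->3');
* sequences are RNA internally (``T`` is normalised to ``U`` on read);
* FASTA headers of orthologous UTRs follow ``gene_id|taxon_id``;
* ortholog tables are sparse long-format TSV — omitted (gene, taxon)
  rows default to "absent";
* result TSVs have a fixed column order and are accompanied by a manifest
  recording seed and configuration hash, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO

from .targeting import SITE_TYPES
from .trees import SpeciesTree

logger = logging.getLogger("regloss")

# IUPAC nucleotide codes (RNA internally); gap handled separately
IUPAC_RNA = frozenset("ACGURYSWKMBDHVN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def get_logger(level: str = "INFO") -> logging.Logger:
    """Package logger with a plain-text handler and level control."""
    log = logging.getLogger("regloss")
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(handler)
    log.setLevel(level.upper())
    return log


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


# ---------------------------------------------------------------------------
# readers


def read_ortholog_table(path) -> pd.DataFrame:
    """Read a sparse gene x taxon ortholog presence table (TSV).

    Required columns: gene_id, taxon_id, present; optional seed_conserved
    (only meaningful for miRNA orthologs).  Unknown columns are ignored
    with a warning.  Returns a validated DataFrame with ``present`` as
    bool and ``seed_conserved`` as nullable boolean.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "taxon_id": str})
    required = {"gene_id", "taxon_id", "present"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    known = required | {"seed_conserved"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)
        df = df.drop(columns=extra)

    dup = df.duplicated(subset=["gene_id", "taxon_id"])
    if dup.any():
        i = int(dup.idxmax())
        raise FormatError(
            f"{path}: duplicate (gene, taxon) pair "
            f"({df.at[i, 'gene_id']}, {df.at[i, 'taxon_id']}) at line {i + 2}"
        )
    df["present"] = df["present"].astype(int).astype(bool)
    if "seed_conserved" in df.columns:
        seed = df["seed_conserved"]
        flag_no_presence = seed.notna() & ~df["present"]
        if flag_no_presence.any():
            i = int(flag_no_presence.idxmax())
            raise FormatError(
                f"{path}: seed_conserved set without presence for "
                f"({df.at[i, 'gene_id']}, {df.at[i, 'taxon_id']}) at line {i + 2}"
            )
        df["seed_conserved"] = seed.map(
            lambda v: v if pd.isna(v) else bool(int(v))
        ).astype("boolean")
    return df.reset_index(drop=True)


def read_newick(path) -> SpeciesTree:
    """Read a single rooted Newick tree with unique leaf labels."""
    return SpeciesTree.read(path)


def write_newick(tree: SpeciesTree, path) -> None:
    tree.write(path)


def read_utr_fasta(path, aligned: bool = False) -> dict[str, dict[str, str]]:
    """Read (optionally aligned) orthologous 3'-UTRs, ``gene|taxon`` headers.

    Sequences are upper-cased and DNA T is normalised to RNA U; the gap
    character ``-`` is only legal when ``aligned``.  Returns
    gene_id -> {taxon_id -> sequence}; aligned groups are checked for
    equal lengths.
    """
    groups: dict[str, dict[str, str]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.id
        if "|" not in header:
            raise FormatError(f"{path}: header {header!r} is not 'gene|taxon'")
        gene_id, taxon_id = header.split("|", 1)
        seq = str(record.seq).upper().replace("T", "U")
        allowed = IUPAC_RNA | ({"-"} if aligned else set())
        bad = set(seq) - allowed
        if bad:
            raise FormatError(
                f"{path}: non-IUPAC character(s) {sorted(bad)} in {header}"
            )
        group = groups.setdefault(gene_id, {})
        if taxon_id in group:
            raise FormatError(f"{path}: duplicate record {header!r}")
        group[taxon_id] = seq
    if aligned:
        for gene_id, group in groups.items():
            lengths = {len(s) for s in group.values()}
            if len(lengths) > 1:
                raise FormatError(
                    f"{path}: unequal aligned lengths {sorted(lengths)} "
                    f"for gene {gene_id}"
                )
    return groups


def write_utr_fasta(groups: Mapping[str, Mapping[str, str]], path) -> None:
    """Write UTR groups as FASTA with ``gene|taxon`` headers (sorted)."""
    with open(path, "w") as fh:
        for gene_id in sorted(groups):
            for taxon_id in sorted(groups[gene_id]):
                fh.write(f">{gene_id}|{taxon_id}\n{groups[gene_id][taxon_id]}\n")


def read_mirna_fasta(path) -> list:
    """Read mature miRNA sequences (RNA or DNA FASTA; T normalised to U).

    The record id is the miRNA id; an optional second whitespace-separated
    token in the description is taken as the family id.
    """
    from .targeting import MatureMiRNA

    matures = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.description.split()
        family = parts[1] if len(parts) > 1 else ""
        seq = str(record.seq).upper().replace("T", "U")
        matures.append(MatureMiRNA(record.id, seq, family_id=family))
    if not matures:
        raise FormatError(f"{path}: no FASTA records")
    return matures


def read_site_scores(
    path, utrs: Mapping[str, Mapping[str, str]] | None = None
) -> pd.DataFrame:
    """Read a per-site context-score table (TargetScan-style TSV).

    Columns: gene_id, mirna_id, site_start, site_end, site_type,
    context_score.  Coordinates are validated against UTR lengths when
    UTR groups are supplied.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_id": str, "mirna_id": str, "site_type": str},
    )
    required = [
        "gene_id",
        "mirna_id",
        "site_start",
        "site_end",
        "site_type",
        "context_score",
    ]
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return df[required]
    df["site_start"] = df["site_start"].astype(int)
    df["site_end"] = df["site_end"].astype(int)
    df["context_score"] = df["context_score"].astype(float)
    bad_iv = df["site_end"] <= df["site_start"]
    if bad_iv.any():
        i = int(bad_iv.idxmax())
        raise FormatError(
            f"{path}: site_end <= site_start at line {i + 2} "
            f"({df.at[i, 'gene_id']}/{df.at[i, 'mirna_id']})"
        )
    bad_type = ~df["site_type"].isin(SITE_TYPES)
    if bad_type.any():
        i = int(bad_type.idxmax())
        raise FormatError(
            f"{path}: unknown site_type {df.at[i, 'site_type']!r} at line {i + 2}"
        )
    if not df["context_score"].map(lambda v: v == v and abs(v) != float("inf")).all():
        raise FormatError(f"{path}: non-finite context_score")
    if utrs is not None:
        for row in df.itertuples(index=False):
            group = utrs.get(row.gene_id)
            if group is None:
                continue
            max_len = max(len(s.replace("-", "")) for s in group.values())
            if row.site_end > max_len:
                raise FormatError(
                    f"{path}: site [{row.site_start},{row.site_end}) exceeds "
                    f"UTR length {max_len} for gene {row.gene_id}"
                )
    return df[required]


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression result table.

    Columns: gene_id, control_reads, log2fc, padj (padj may be missing
    for genes removed by independent filtering).  gene_id must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "control_reads", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["gene_id"])
    if dup.any():
        i = int(dup.idxmax())
        raise FormatError(f"{path}: duplicate gene_id {df.at[i, 'gene_id']!r}")
    df["control_reads"] = df["control_reads"].astype(float)
    if (df["control_reads"] < 0).any():
        raise FormatError(f"{path}: negative control_reads")
    df["log2fc"] = df["log2fc"].astype(float)
    df["padj"] = df["padj"].astype(float)
    valid = df["padj"].isna() | ((df["padj"] >= 0) & (df["padj"] <= 1))
    if not valid.all():
        raise FormatError(f"{path}: padj outside [0, 1]")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# writers


def _config_hash(config: Mapping | None) -> str:
    canonical = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    seed: int | None = None,
    config: Mapping | None = None,
) -> list[Path]:
    """Write result tables as TSV plus a run manifest.

    Each table is written as ``<name>.tsv`` with its existing column
    order; the manifest records the RNG seed, a configuration hash and
    row counts — but no timestamps — so identical runs are byte-identical.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []
    for name in sorted(tables):
        path = out / f"{name}.tsv"
        tables[name].to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)
    manifest = {
        "package": "regloss 0.1.0",
        "seed": seed,
        "config_sha256": _config_hash(config),
        "tables": {name: int(len(tables[name])) for name in sorted(tables)},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    written.append(manifest_path)
    return written
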