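"""miRNA seed extraction, canonical seed-site scanning and target calling.

The seed of a mature miRNA is nucleotides 2-8 (5'->3').  Canonical site
types on the mRNA, written 5'->3' in mRNA sense, follow the TargetScan
taxonomy:

========  ======================================  ==========
type      mRNA pattern                            length
========  ======================================  ==========
8mer      revcomp(seed2-8) + 'A'                  8
7mer-m8   revcomp(seed2-8)                        7
7mer-A1   revcomp(seed2-7) + 'A'                  7
6mer      revcomp(seed2-7)                        6
========  ======================================  ==========

so the 6mer core is a suffix of the 7mer-m8 pattern (the extra match to
miRNA position 8 sits at the site's 5' end) and every site contains one
6mer core.  Scanning reports each core occurrence exactly once, labelled
with the longest applicable type at that locus.

Per-site context++-style scores are aggregated per gene x miRNA into a
total context score ``tc``; a gene is a predicted target when ``tc`` is at
or below a (negative) threshold, more negative meaning stronger predicted
repression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}

DEFAULT_TC_THRESHOLD = -0.2


def revcomp_rna(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence (RNA, 5'->3')."""

    mirna_id: str
    sequence: str
    family_id: str = ""

    def __post_init__(self) -> None:
        if set(self.sequence) - RNA_ALPHABET:
            bad = sorted(set(self.sequence) - RNA_ALPHABET)
            raise ValueError(f"{self.mirna_id}: non-RNA characters {bad}")
        if len(self.sequence) < 18:
            raise ValueError(
                f"{self.mirna_id}: mature sequence shorter than 18 nt "
                f"({len(self.sequence)})"
            )


@dataclass(frozen=True)
class Seed:
    """Nucleotides 2-8 of a mature miRNA (7 nt)."""

    mirna_id: str
    seed7: str

    def __post_init__(self) -> None:
        if len(self.seed7) != 7:
            raise ValueError("seed must be exactly 7 nt")
        if set(self.seed7) - RNA_ALPHABET:
            raise ValueError("seed contains non-RNA characters")


@dataclass(frozen=True)
class SeedSite:
    """One located seed-match site in a UTR (0-based, half-open)."""

    start: int
    end: int
    site_type: str
    mirna_id: str = ""
    gene_id: str = ""
    taxon_id: str = ""

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start != SITE_LENGTH[self.site_type]:
            raise ValueError(
                f"site [{self.start},{self.end}) has wrong length for "
                f"{self.site_type}"
            )


def extract_seed(mirna: MatureMiRNA | str, mirna_id: str = "") -> Seed:
    """Seed = positions 2-8 (1-based) of the mature sequence."""
    if isinstance(mirna, MatureMiRNA):
        seq, mirna_id = mirna.sequence, mirna.mirna_id
    else:
        seq = mirna
    if len(seq) < 8:
        raise ValueError(f"mature sequence too short for a seed: {len(seq)} nt")
    return Seed(mirna_id=mirna_id, seed7=seq[1:8])


def site_patterns(seed: Seed) -> dict[str, str]:
    """mRNA-sense (5'->3') match patterns for the four canonical site types."""
    p7m8 = revcomp_rna(seed.seed7)
    core6 = revcomp_rna(seed.seed7[:6])
    return {
        "8mer": p7m8 + "A",
        "7mer-m8": p7m8,
        "7mer-A1": core6 + "A",
        "6mer": core6,
    }


def scan_utr(utr: str, seed: Seed) -> list[SeedSite]:
    """Find all canonical seed-match sites in a gap-free RNA UTR.

    Each occurrence of the 6mer core defines one locus; the locus is
    reported once with the longest applicable type (an 8mer is not
    additionally reported as 7mer or 6mer).  Sites are sorted by start.
    """
    if len(utr) < 6:
        return []
    bad = set(utr) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters in UTR: {sorted(bad)}")
    pats = site_patterns(seed)
    core = pats["6mer"]
    m8 = pats["7mer-m8"][0]
    sites: list[SeedSite] = []
    j = utr.find(core)
    while j != -1:
        has_m8 = j > 0 and utr[j - 1] == m8
        has_a1 = j + 6 < len(utr) and utr[j + 6] == "A"
        if has_m8 and has_a1:
            site = SeedSite(j - 1, j + 7, "8mer", mirna_id=seed.mirna_id)
        elif has_m8:
            site = SeedSite(j - 1, j + 6, "7mer-m8", mirna_id=seed.mirna_id)
        elif has_a1:
            site = SeedSite(j, j + 7, "7mer-A1", mirna_id=seed.mirna_id)
        else:
            site = SeedSite(j, j + 6, "6mer", mirna_id=seed.mirna_id)
        sites.append(site)
        j = utr.find(core, j + 1)
    sites.sort(key=lambda s: s.start)
    return sites


@dataclass(frozen=True)
class GeneTargetScore:
    """Total context score of one gene for one miRNA."""

    gene_id: str
    mirna_id: str
    tc: float
    is_predicted_target: bool


def aggregate_tc(
    scores: Iterable[float],
    threshold: float = DEFAULT_TC_THRESHOLD,
    gene_id: str = "",
    mirna_id: str = "",
) -> GeneTargetScore:
    """Sum per-site context scores; target iff the total is <= threshold.

    A gene without sites has tc 0 and is never a target (the threshold is
    negative).  The comparison is inclusive at the threshold.
    """
    tc = float(sum(scores))
    return GeneTargetScore(
        gene_id=gene_id, mirna_id=mirna_id, tc=tc, is_predicted_target=tc <= threshold
    )


def aggregate_tc_table(
    site_scores: pd.DataFrame, threshold: float = DEFAULT_TC_THRESHOLD
) -> pd.DataFrame:
    """Per gene x miRNA totals from a per-site score table.

    Returns columns gene_id, mirna_id, n_sites, tc, is_predicted_target,
    sorted for reproducible output.
    """
    if site_scores.empty:
        return pd.DataFrame(
            columns=["gene_id", "mirna_id", "n_sites", "tc", "is_predicted_target"]
        )
    grouped = (
        site_scores.groupby(["gene_id", "mirna_id"], sort=True)["context_score"]
        .agg(n_sites="size", tc="sum")
        .reset_index()
    )
    grouped["tc"] = grouped["tc"].astype(float)
    grouped["is_predicted_target"] = grouped["tc"] <= threshold
    return grouped


def _best_ungapped_match(a: str, b: str, max_mismatch: int) -> tuple[int, int]:
    """Longest ungapped local match between two sequences with at most
    ``max_mismatch`` mismatches; returns (length, mismatches used)."""
    best = (0, 0)
    for offset in range(-(len(b) - 1), len(a)):
        # positions i in a, i - offset in b along one diagonal
        lo = max(0, offset)
        hi = min(len(a), len(b) + offset)
        if hi - lo < best[0]:
            continue
        mismatch_pos: list[int] = []
        left = lo
        for i in range(lo, hi):
            if a[i] != b[i - offset]:
                mismatch_pos.append(i)
                if len(mismatch_pos) > max_mismatch:
                    left = mismatch_pos.pop(0) + 1
            length = i - left + 1
            if (length, -len(mismatch_pos)) > (best[0], -best[1]):
                best = (length, len(mismatch_pos))
    return best


def compensation_scan(
    lost: Sequence[MatureMiRNA],
    extant: Sequence[MatureMiRNA],
    mode: str = "seed_exact",
    min_match_len: int = 14,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Scan an extant miRNA set for potential functional compensation.

    ``seed_exact`` reports extant miRNAs whose 7-nt seed is identical to a
    lost miRNA's seed (same canonical target repertoire).  ``short_match``
    reports near-identity over the mature sequences: an ungapped local
    match of at least ``min_match_len`` nt with at most ``max_mismatch``
    mismatches, a deterministic surrogate for a short-word nucleotide
    BLAST at a stringent E-value.  Returns a (possibly empty) hit table.
    """
    if mode not in ("seed_exact", "short_match"):
        raise ValueError(f"unknown mode {mode!r}")
    if not lost or not extant:
        raise ValueError("both miRNA sets must be non-empty")
    hits: list[dict] = []
    for lm in lost:
        lseed = extract_seed(lm).seed7
        for em in extant:
            if mode == "seed_exact":
                if extract_seed(em).seed7 == lseed:
                    hits.append(
                        {
                            "lost_id": lm.mirna_id,
                            "extant_id": em.mirna_id,
                            "mode": mode,
                            "evidence": f"seed={lseed}",
                        }
                    )
            else:
                length, mm = _best_ungapped_match(
                    lm.sequence, em.sequence, max_mismatch
                )
                if length >= min_match_len:
                    hits.append(
                        {
                            "lost_id": lm.mirna_id,
                            "extant_id": em.mirna_id,
                            "mode": mode,
                            "evidence": f"match_len={length},mismatches={mm}",
                        }
                    )
    return pd.DataFrame(hits, columns=["lost_id", "extant_id", "mode", "evidence"])
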