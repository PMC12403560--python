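"""Scan a 3'-UTR for canonical miRNA seed-match sites and call targets.

Uses the mature sequence of miR-197-3p: the seed is nucleotides 2-8, and
the canonical site types (8mer > 7mer-m8 / 7mer-A1 > 6mer) are matched on
the mRNA 5'->3'.  Per-site context scores are summed into a total context
score; a gene is a predicted target when the total is at or below -0.2.
"""

from regloss import aggregate_tc, extract_seed, scan_utr, site_patterns

mature = "UUCACCACCUUCUCCACCCAGC"  # miR-197-3p
seed = extract_seed(mature, "mir197")
print(f"mature {mature}  ->  seed (pos 2-8): {seed.seed7}")
print("site patterns:", site_patterns(seed))

utr = "GGCAGUGGUGAACCAUUUGUGGUGAGGGCCCGUGGUGAC"
for site in scan_utr(utr, seed):
    print(f"  {site.site_type:8s} at [{site.start},{site.end})  "
          f"matched: {utr[site.start:site.end]}")

score = aggregate_tc([-0.15, -0.10], gene_id="g1", mirna_id="mir197")
print(f"total context score {score.tc:+.2f} -> predicted target: "
      f"{score.is_predicted_target}")
# Two weak sites (-0.15, -0.10) jointly cross the -0.2 threshold: target
# calling is cumulative over all sites of a gene's UTR.
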