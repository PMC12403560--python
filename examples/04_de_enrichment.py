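"""Classify differentially expressed genes and test target enrichment.

Simulates a DE table after miRNA overexpression (true targets planted at
log2FC -2), applies the filters (|log2FC| > 0.5, >= 100 control reads,
BH-adjusted p <= 0.05), and compares the number of predicted targets in
the down-regulated set against a 1,000-resample null.
"""

from regloss import SimConfig, classify_de, resample_enrichment
from regloss.simulate import simulate_de

cfg = SimConfig(rng_seed=42, n_de_genes=1000, de_effect=2.0,
                fraction_true_targets=0.05)
table, truth = simulate_de(cfg)
sets = classify_de(table)
print(f"expressed universe: {len(sets.universe)} genes; "
      f"down: {len(sets.down)}, up: {len(sets.up)}")

targets = set(truth.true_targets) & sets.universe
res = resample_enrichment(sets.down, targets, sets.universe, n=1000, seed=7)
print(f"targets in down-set: observed {res.observed}, "
      f"null {res.null_mean:.2f} +/- {res.null_sd:.2f}")
print(f"Z = {res.z:.1f}, two-sided p = {res.p_two_sided:.3g} "
      f"(exact hypergeometric: {res.p_exact:.3g})")
# A Z-score far above the resampled null shows the down-regulated genes
# are packed with predicted targets — the signature of direct repression
# by the overexpressed miRNA, as opposed to indirect effects in the
# up-regulated set.
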