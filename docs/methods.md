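# Methods

This note documents the models, parameter choices and numerical conventions
behind `regloss`, and what the synthetic-data experiments do and do not
demonstrate.

## Phylogenetic profiles and co-loss mining

A profile matrix holds one ternary state per (gene, taxon): absent, present
with divergent seed, present with conserved seed (protein-coding genes use
only absent/present). Binarization maps conserved presence to 1 and, by
default, divergent-seed presence to 0, because an ortholog whose seed has
changed no longer recognises the ancestral target repertoire.

Similarity between binary profiles is the Pearson correlation, which equals
the phi coefficient of the 2×2 co-occurrence table. Constant profiles have
an undefined correlation (zero denominator); they are flagged as undefined
and excluded from ranking rather than assigned 0, since a gene present
everywhere carries no co-loss signal. Ranking is per miRNA: the top
`percentile` percent (default 1.0%) of genes by *r*, with every gene tied
at the cutoff value included — ties are never broken arbitrarily. A gene is
reported as co-lost when it is similar to at least `ceil(min_fraction · M)`
of the M miRNA profiles; "at least half" of 15 therefore means 8, since 7
of 15 is less than half. The percentile is a per-miRNA rank cut, not a
global *r*-threshold.

Loss-branch characterisation uses Dollo parsimony: miRNA families are
assumed homologous (one origin), so the gain sits on the edge above the LCA
of all carriers and each maximal all-absent subtree below it is one
independent loss. Branches are identified by the sorted leaf set below
them.

Annotation-set enrichment (e.g. transcription factors among co-lost genes)
uses the two-sided Fisher exact test with fold enrichment
(hits/set)/(hits_universe/universe); an empty hit universe reports fold 0
with p = 1. The ubiquity filter calls a gene ubiquitous when present in
strictly more than `threshold` (default 95%) of taxa.

## Seed sites and target calling

Site geometry follows the canonical TargetScan taxonomy with the seed at
mature positions 2–8. In mRNA sense the m8-match extends the 6mer core at
its 5' end and the A1 anchor at its 3' end, so the 6mer core is a suffix of
the 7mer-m8 pattern and every site type contains exactly one core
occurrence. The scanner therefore anchors on core occurrences and assigns
each locus the longest applicable type — an 8mer is not additionally
counted as 7mer or 6mer, which prevents double counting in dating and
enrichment. Coordinates are 0-based half-open on the UTR sense strand;
sequences are RNA internally (T→U on read). Non-nucleotide characters are
an error rather than a skip, so sites can never silently span fragment
junctions.

The total context score per gene × miRNA is the plain sum of per-site
context scores (consumed as input; the feature regression that produces
them is out of scope). The target threshold is tc ≤ −0.2, inclusive at the
boundary: context scores are negative for repression, so "minimum
threshold" is read on the repression scale. The threshold is configurable.

The compensation scan has two modes: exact seed identity, and a
deterministic surrogate for a short-word nucleotide BLAST — the longest
ungapped local match between mature sequences, hit when ≥ 14 nt with ≤ 1
mismatch. At mature-miRNA length (~22 nt) this is conservative: any
alignment a short-word BLAST would report as significant at stringent
E-values contains such a run. Both parameters are configurable.

## Site homology and parsimony dating

Sites are called per species on ungapped UTRs and projected into the
columns of the supplied alignment (the package does not embed an MSA tool;
hiding alignment error inside the method would make dating accuracy
unattributable). Homology requires at least one shared alignment column —
the weakest reading of "overlapping" — with transitive closure into groups;
no overlap fraction is imposed because none is justified a priori. Site
types are grouped and dated separately: 8mer and 6mer characters have very
different gain/loss dynamics and merging them would blur exactly the
contrast of interest.

Dollo dating places the gain above the LCA of carriers. Wagner dating runs
Sankoff dynamic programming over {absent, present} with edge costs
`gain_cost` (default 2) and `loss_cost` (default 1); a virtual absent
ancestor above the root makes a root-state-present labelling pay one gain
on the root branch. Of the minimum-cost labellings the root-most realisable
gain edge is reported (ties among equally deep branches break
lexicographically by branch id), and the implied losses come from one
optimal labelling whose tie-breaks keep the parent state, so event counts
are never inflated. The default 2:1 asymmetry discourages convergent-gain
explanations while still allowing them when losses would be numerous; with
a prohibitive gain cost Wagner reduces exactly to Dollo.

Age classification relates a gain branch to a two-species split: at or
before their LCA, or inside either lineage. A gain branch outside the
split's clade (possible when carriers are all outgroup taxa) raises an
error rather than guessing a side.

## Expression response

DE filters: |log2FC| strictly greater than 0.5, at least 100 normalized
reads in the negative control, BH-adjusted p at most 0.05. The enrichment
universe is the expressed transcriptome — genes passing the reads filter
with a defined adjusted p; genes removed by independent filtering are not
part of the tested pool. Resampling draws uniform without-replacement gene
sets of the DE-set size; the observed target count is converted to a
two-sided normal p through the null's Z-score, with the exact
hypergeometric p always reported alongside (and used outright when the
null is degenerate). Empirical overlap p-values use the (r+1)/(n+1)
pseudocount, so they are never zero and are reproducible bit-for-bit given
the seed. For cross-species overlap the empirical null resamples one set's
size (the other held fixed); the overlap count of a uniform draw is
hypergeometric and is sampled directly, which is distributionally
identical to materialising each gene set and fast enough for n = 10⁶.
The tissue-expression similarity statistic is the mean pairwise Pearson r
of the focal genes' expression vectors against same-size random gene sets;
constant rows are excluded with a warning.

## Synthetic data: what it emulates and what it does not

The generators' defaults are the study conditions: 60 taxa, 1,000 protein
genes with 20 planted co-lost among them, 15 focal miRNA families lost on
the stem of a planted ~8-taxon clade, background loss rate 0.02/branch;
UTRs of 300 nt evolved at 0.01 substitutions/site/branch; DE tables of
1,000 genes with 5% true targets at log2FC −2 (noise sd 0.25), control
reads log-normal with median 600 and σ = 0.8 — chosen so the bulk of the
transcriptome clears the 100-read filter, as in a typical polyA library.

Design choices that keep the ground truth identifiable:

* **Planted entities carry the exact clade-absence pattern.** Background
  losses apply only to unplanted genes, and the background process skips
  the planted stem branch. Otherwise a background gene can, by chance,
  lose on exactly the planted stem and become indistinguishable from a
  planted gene — at 0.02/branch on a ~118-branch tree roughly 2 per 1,000
  genes — which would make "precision against the planted truth"
  ill-defined. Chance near-misses elsewhere in the tree remain and are the
  null cohort the miner must reject.
* **Substitution-only UTR evolution** (Jukes–Cantor-style uniform choice
  among the three alternatives) so the true alignment is the identity
  alignment and dating error is attributable to the method, not to an
  aligner. A gain is "clean" when re-scanning shows the planted-type site
  present in exactly the planted clade with no convergent gains at the
  locus; dating recovery is scored over groups that retain the site in at
  least one species (a fully eroded character leaves nothing to date).
* **DE p-values come from the known noise model**, BH-adjusted — the
  pipeline consumes DE statistics, it never fits count models. The three
  filter-boundary sentinels (log2FC = 0.5, padj = 0.05, reads = 99) are
  appended with literal values because an exact adjusted p cannot be
  planted through the BH computation.

Passing tests on these data show that the algorithms recover planted
signal under their own model assumptions. They do not show robustness to
what real data add: alignment error and indels, lineage-specific rate
variation, correlated gene losses, expression-matched DE nulls, or
non-canonical target sites — all declared out of scope.

## Numerical conventions and problem sizes

Profiles, sites and DE tables round-trip through TSV with fixed column
order; result directories include a manifest (seed, configuration hash, row
counts, no timestamps) so identical runs are byte-identical. Oracle
comparisons in the test-suite and acceptance script use exhaustive
enumeration where feasible (all 2⁸−1 presence patterns on 8-leaf trees for
Dollo; all internal labellings on 6-leaf trees for Wagner; all length-4
binary vector pairs for phi) and seeded random cohorts elsewhere (1,000
random 500-nt UTRs × 50 seeds for the scanner; 50 configurations for the
resampling-null calibration; 200 UTR groups for dating recovery) — sizes at
which every check completes in seconds on one CPU.
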