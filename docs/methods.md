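# Methods

## Scope and data model

The package operates strictly downstream of assembly, binning, and
annotation. Its inputs are four tab-separated tables per survey —

* per-gene annotation rows `(mag_id, gene_symbol, scaffold_id,
  scaffold_length)`, where a gene may appear multiple times (multi-copy);
* per-MAG pathway completion `(mag_id, pathway_id, steps_present,
  steps_total)`;
* GTDB taxonomy, as a seven-rank lineage string or rank columns;
* per-scaffold mean read depth `(site_id, mag_id, scaffold_id, coverage)`;

plus, for the meta-analysis, per-study taxon reports `(study_id, method,
taxon_name, rank_claimed)`. Gene symbols are validated against an editable
vocabulary file that also maps annotation-tool dialect labels (e.g. the
"acetate pt. 1/2" sheet labels) onto canonical symbols; unknown tokens are
reported, never dropped. Pathway completion is stored as an exact rational
(`steps_present / steps_total`), so threshold comparisons such as
6/8-versus-75 % are decided without floating-point ambiguity.

## Abundance

Mean MAG coverage is the **unweighted** arithmetic mean over its unique
scaffolds; a length-weighted alternative was considered and rejected as the
default because per-scaffold mean depths are already length-normalized by
the mapper. Relative abundance at a site is the MAG's mean coverage over
the site's summed mean coverage, ×100. Rank aggregation sums percentages
within taxon names; MAGs unclassified at the rank pool under
`unclassified_<rank>`, so the total is conserved at 100 (enforced to 1e-9
relative in tests). Values are kept at full precision internally and
rounded only for display.

## Guild rules

Thresholds live in one configurable record (`RuleThresholds`). Two
deliberate asymmetries:

* the 75 % hydrogenotrophic bar is **inclusive** (≥ 6/8): the stated 6/8
  equivalence would otherwise contradict a strict "> 75 %" reading;
* the 50 % CODH/ACS bar is **exclusive** (> 1/2): with a 2-step module only
  2/2 qualifies, matching the 2/2 usage in the acetogen categories;
* "lacks the CODH/ACS complex" is read as completion exactly 0, not ≤ 50 %.

The four methanogen rules are evaluated in a fixed order
(broad-substrate → methylotrophic → acetoclastic → strict). The order is
this package's decision — most-specific first. Its consequences are made
inspectable by `audit_rule_overlap`, which enumerates the full feature grid
(5 *mcr* booleans × 9 hydrogenotrophic step counts × 3 CODH/ACS step counts
× 2 acetate booleans × 4 methyl-substrate booleans × *mtsA*/*mtaA*;
221,184 cells) and reports the cells on which more than one rule fires.
Exactly two pair overlaps exist (broad ∧ acetoclastic: 8,640 cells;
methylotrophic ∧ strict: 4,032 cells), and the tests pin both the set and
the counts. Acetate activation accepts either gene-pair dialect:
acetyl-CoA synthetase alone, or acetate kinase together with an
acetyltransferase or phosphotransacetylase. Methylthiol-driven calls
(*mtsA*/*mtaA* with no canonical methyl substrate) are labelled
methylotrophic with a dedicated flag. H₂-dependent versus
disproportionating methylotrophy is deliberately not modelled.

Methanotroph identification requires only the key subunits (*pmoA*,
*mmoX*); sMMO operon completeness is reported but never required, because
*mmoZ* diverges even in bona fide methanotrophs. The novel-family
verification bar ("multiple genes on ~3 kbp scaffolds") is fixed at ≥ 2
pMMO/sMMO-operon gene observations on scaffolds of ≥ 3000 bp each, without
requiring co-location on one scaffold — the weaker reading; both constants
are configurable. Unverified calls are retained and flagged rather than
dropped. ANME calls are taxonomy-driven and tallied separately from the
aerobic modes.

## Ordination

Bray-Curtis dissimilarities are computed with scipy over the union feature
space (absent taxon = 0); two all-zero profiles are an error, not a NaN.
The NMDS optimizer is iterative majorization: per iteration, configuration
distances are monotone-regressed on the input dissimilarities
(pool-adjacent-violators via isotonic regression, ties averaged within
equal-dissimilarity blocks — the weak/secondary treatment), disparities are
rescaled to the configuration's distance norm, and a Guttman transform
updates the configuration. Raw stress is non-increasing within a restart;
convergence is declared at a relative raw-stress change below 1e-7 or 300
iterations. The reported figure is Kruskal stress-1. "N restarts" means N
independent random initializations from one seeded generator with the
minimum-stress result returned, which reproduces the convention of the
standard community-ecology implementation; on identical distance matrices
the stress agrees with R's `vegan::metaMDS` to ~1e-8 (tested). Coordinates
are centered, rotated to principal axes, and sign-fixed so runs are
byte-reproducible.

Degenerate inputs: exactly embeddable distances reach stress < 1e-6;
strongly clustered communities (like the synthetic site groups below) can
legitimately embed with stress ≈ 0, a known NMDS behaviour on two-cluster
data — real surveys with gradient structure report small but nonzero
stress.

## Occurrence meta-analysis

Harmonization is an exact lookup after whitespace/case normalization in a
versioned, human-editable synonym table shipped with the package (legacy
species and genus names map through their family; current GTDB families are
fixed points, so harmonization is idempotent). Unmapped names resolve to
`UNRESOLVED` and never create families. Studies whose reports all fail to
reach family level are discarded before the presence matrix is built;
presence is liberal (any resolvable report). The pipeline's own methanogen
calls enter the compilation as an ordinary study, so the denominator counts
this survey too.

## Synthetic data generator

Each planted guild class has a gene/pathway template chosen to be exactly
recoverable by the rules at default thresholds (verified by a noise-free
recovery test across all classes). Coverage is lognormal per MAG (μ = 2,
σ = 1 on the log scale) with multiplicative per-scaffold jitter
(σ = 0.2) — heavy-tailed enough to produce the dominant-MAG structure real
leachate communities show. Scaffold counts are uniform on [5, 30] and
lengths uniform on [2.5, 50] kbp, respecting a 2.5 kbp assembly inclusion
floor; pMMO/sMMO marker genes are placed on scaffolds ≥ 3.1 kbp so planted
methanotrophs pass verification. Background MAGs draw families from an
"older-site" or "newer-site" pool whose weights get a per-site lognormal
tilt (σ = 0.5), giving between-group compositional separation with
within-group variability.

The noise model (`degrade`) drops each annotation row independently with
probability *p*; spurious additions are available behind a separate
parameter, off by default, so that recovery under the default model has a
closed form. For each class the exact recovery probability is obtained by
enumerating gene-survival patterns and re-running the rules
(`class_recovery_probability`); the test suite independently re-derives the
per-class closed forms (e.g. strict hydrogenotrophs survive at 1 − p³,
acetoclastic at (1 − p²)(1 − p)) and the Monte-Carlo recovery over 20 seeds
must sit inside a 4-σ binomial interval of the analytic expectation.

What passing these tests shows — and does not. The generator reproduces the
presence/absence logic, pathway step structure, and coverage statistics the
pipeline consumes; it does not emulate annotation-tool miscalls that are
correlated across genes, chimeric bins, partial-gene fragments, or
databases drifting between taxonomy releases. Perfect recovery at zero
noise validates the rule engine's internal consistency, not annotation
accuracy on real genomes.

The **study-scale configuration** (`study_scale_config`) is a synthetic
stand-in for a real eight-site decadal landfill survey: per-site MAG totals
(93–294, 1647 in all), per-site methanogen guild composition (79 labelled
methanogens; 20 at site F1, 17 at site D2), 31 aerobic methanotrophs split
15/5/11 between pMMO-only, sMMO-only and both, two ANME MAGs at one older
site, redox-trait counts of 27 (nitrite reduction), 24 (high-affinity
complex IV) and 26 (low-affinity) of 31, and a 22-study literature
compilation planted so that after harmonization and the discard rule,
*Methanosarcinaceae* occurs in 17 of 21 retained studies and
*Methanotrichaceae* in 15 of 21. All of these figures are generator inputs;
the acceptance script's value is demonstrating that the pipeline recomputes
each of them from the raw tables alone.

## Problem sizes and numerical choices

The acceptance script runs the full feature-grid audit (221,184 cells), the
recovery experiment at 8 sites × 150 MAGs × 20 noise seeds, and the
1647-MAG study-scale pipeline — about half a minute on one CPU. NMDS uses
20 restarts and k = 2 throughout. Seeds control every random draw; derived
seeds stay below 2³¹. Tie-breaks are deterministic everywhere (stable
sorts, sorted iteration orders), so identical inputs give byte-identical
outputs, which the manifest (input digests, seed, version) makes checkable.

## Known limitations

* Guild labels are genomic potential, not activity; lineages that carry
  acetate-activation genes for assimilation (e.g. *Methanoculleus*-type
  physiology) will be called acetoclastic regardless.
* The synonym table covers the methanogen/ANME families and their common
  legacy names; meta-analyses of other clades need table extensions.
* Abundance assumes coverage is comparable within a site; no
  between-survey normalization is attempted.
* The CLI reads whole tables into memory; surveys beyond ~10⁶ annotation
  rows may want chunked readers.
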