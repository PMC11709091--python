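# Methods

## The design the pipeline assumes

Donors are stratified into six groups by biological sex (M/F) and age band
(young ≈ 22–35, middle-aged ≈ 41–55, old ≈ 64–79 years, with slightly
different recruitment ranges per sex). Equal plasma volumes (0.5 mL) from
four donors of one group are physically mixed into a pool; five pools are
formed per group (30 pools), and the first three per group are carried to
proteomics (18 pools). Each proteomics pool is separated by size-exclusion
chromatography into an EV-enriched and a protein-enriched fraction, so the
quantification data are two proteins × 18-pool matrices. Which three of
the five pools go to proteomics is not identifiable from the design, so
the simulator's "first k pools" convention is an arbitrary labelling, not
a claim about the emulated study.

A pool is one biological sample: within-group replication is n = 3 (or
n = 5 for plasma-level measurements), and donor-level variance is partly
averaged away by pooling. The analysis rules below are built around that
constraint.

## Ratio-sign-consistency differential abundance

For two pool sets A (m pools) and B (n pools) and one protein, all m×n
cross ratios a_i/b_j are formed; the protein is DE "up" iff every ratio is
strictly greater than 1, "down" iff every ratio is strictly less than 1.
Equivalent formulation: up ⇔ min(A) > max(B). The paired EV-vs-PROT rule
is the within-pool analogue: one EV/PROT ratio per matched pool, all 18 on
the same side of 1.

Properties the implementation guarantees and tests:

- **Ties break consistency.** A ratio of exactly 1 defeats both
  directions (the rule is "strictly >1 or <1"), so identical values give
  `not_DE`, and the zero-noise/zero-effect simulation yields exactly zero
  calls.
- **Missingness.** A protein missing (not detected) in any pool of either
  compared set is `not_evaluable` rather than imputed: the complete ratio
  set (9 or 18 ratios) the rule is defined over does not exist. A
  configurable alternative (`require_detected_in="all"`) additionally
  demands detection in every pool of the table.
- **log2 fold change** is the mean of the log2 cross ratios (the log2
  geometric-mean ratio, equal to mean log2(A) − mean log2(B)). It is
  symmetric under group swap and unaffected by ratio ties; no external
  definition of the plotted fold change was available, and this choice is
  the standard one.
- **"Up" means higher in the first-named group** of a comparison label
  (`M:young_vs_old`: up = higher in young; `young:M_vs_F`: up = higher
  in males).
- Group sizes are not hard-coded: 3 vs 3 (nine ratios) is the default
  instantiation, and the null rate generalises.

Under exchangeability with continuous values, P(all m×n ratios one
direction) = 2/C(m+n, m): min(A) > max(B) happens exactly when the top m
order statistics all fall in A, one of C(m+n, m) equally likely
assignments. For the paired rule with independent symmetric ratio
directions, P = 2·(1/2)ⁿ. These are exposed as `null_consistency_rate`
and `null_paired_rate` and verified in tests both by exhaustive
enumeration of orderings at small m, n and by Monte-Carlo runs of the
actual DE functions on exchangeable data (10⁴ replicates for the 3-vs-3
rule, 2×10⁵ for the 18-pool paired rule, agreement within three binomial
standard errors).

The rule has no per-protein p-value machinery beyond these analytic
rates; that is deliberate scope, not an omission.

## Detection filter

A protein is retained iff detected (present and > 0) in **strictly more
than** a threshold fraction (default 0.8) of the fraction's pools,
computed per fraction over all of its pools jointly. With 18 pools the
strictness matters: 15/18 (83.3 %) passes, 14/18 (77.8 %) does not. The
per-group alternative reading is available by filtering a pool-subset
table. The filter is idempotent and monotone in the threshold.

## Set analyses

- **Venn regions** of 2–4 named protein sets report exclusive-region
  counts and percentages of the union, rounded half-up to one decimal
  (two decimals where finer percentages are quoted); percentages always
  recompute exactly from the counts.
- **Age-dynamic proteins** (per sex and fraction): DE in ≥ 2 of the three
  age contrasts by default. The source analyses phrase the cut both as
  "at least two" and "more than two"; the inclusive reading is the
  default and the stricter one is the `min_comparisons=3` flag.
- **Sex-common age proteins**: DE in both sexes for at least one *common*
  age comparison with the *same direction* (the DE definition is
  directional), intersected with the union of the two sexes' age-dynamic
  sets; per-protein provenance (supporting comparisons and directions) is
  recorded. An any-comparison-per-sex variant is available
  (`same_comparison=False`).
- **Sex-consistent proteins**: DE between M and F in all three age groups
  with the same direction.

## Group statistics

Fisher's LSD: pairwise t statistics using the pooled one-way-ANOVA
within-group mean square, df = N − k, two-sided p from Student's t. Tests
are *unprotected* (reported per pair regardless of the omnibus F, which is
shown alongside) because the measurements are displayed with per-pair
significance bands; a Bonferroni option exists and is off by default. At
k = 2 the procedure reduces exactly to the pooled-variance two-sample
t-test, which is the cross-check used in tests (scipy as the independent
oracle). Zero pooled variance with equal means is reported as t = 0,
p = 1.

Particle-count normalization: particles/mL plasma =
measured concentration × dilution factor × prep volume / plasma input
volume (default 0.6 mL concentrate from 2 mL plasma). Linear in the
measured concentration by construction.

## Clustering

Rows (proteins) are z-scored on log2 values (zero-variance rows become
all-zero); rows and columns are clustered agglomeratively on the z-scored
matrix. Defaults are Pearson-correlation distance with average linkage —
the common heatmap-tool configuration; the tool actually used by the
emulated study is unnamed beyond the software, so distance
(euclidean/correlation) and linkage (average/complete/ward) are flags.
Determinism: inputs are sorted by identifier before linkage so distance
ties always resolve identically. Zero-variance rows under correlation
distance receive the maximal distance (2.0) with a warning; proteins with
missing values in the selected pools are dropped with a warning since
their distances are undefined. Flat cluster labels come from a maxclust
cut; dendrograms export as Newick with merge-height branch lengths.

## Synthetic-data generator

Log2-scale generative model per protein p, donor d in group g:

    x_pd = baseline_p + age_offset_p(g) + sex_offset_p(g) + ε_pd

with baseline_p ~ N(baseline_mean, baseline_sd²) across proteins (default
20 ± 2 log2 units, i.e. MaxLFQ-like intensities around 10⁶) and donor
noise ε ~ N(0, donor_sd²) (default 0.5). A pool is the **linear-scale
mean** of its four donors (physical mixing of equal volumes), measured
per fraction with technical noise N(0, tech_sd²) (default 0.2) plus a
fraction offset: EV-enriched proteins (default 45 % of the panel) gain
`ev_enrichment_log2` (default 2) in the EV fraction, PROT-enriched
proteins (default 15 %) the same in PROT. Values whose log2 falls below
`lod_log2` (default 12, a floor about eight log2 units below typical
abundance) are censored to missing after noise — detection-limit dropout,
not zeros. Age effects are per-age-group offsets with a sex scope
(M-only / F-only / both); sex effects are constant M-minus-F offsets per
age group. `random_effects` places sparse effects with young/mid/old
offsets 0, ±e, ±2e so that every pairwise age contrast carries at least
`e`; "4× the donor SD" recovery conditions use e = 2 with donor SD 0.5.

Ages are uniform integers within each group's recruitment range, and
pooling deals age-sorted donors round-robin across pools, emulating the
balanced-age pooling of the design.

What the generator does **not** emulate: peptide-level quantification and
shared-peptide inference, normalization artefacts, batch effects beyond a
single technical term, correlated protein modules, heavy-tailed or
intensity-dependent noise, and informative (abundance-correlated beyond
the hard threshold) missingness. Passing recovery tests therefore show
that the rules behave as designed under the stated stochastic model — not
that real plasma proteomics satisfies that model.

## Calibration and recovery measurements

`poolfrac.evaluate` measures, at the default design (3 pools of 4 donors
per group):

- empirical null rates of the actual DE functions on exchangeable data
  (see above);
- sensitivity and false-positive rate against ground truth with pairwise
  effects at 4× the donor SD: 2000 proteins, 100 age-affected and 50
  sex-affected, scoring every (protein, comparison, fraction)
  combination. Sensitivity lands near 0.99 and the false-positive rate at
  the analytic 0.1 within Monte-Carlo error; comparisons share pools, so
  the pooled rate is judged against a single comparison's binomial SE
  (conservative).

Problem sizes throughout the tests and the acceptance script (10⁴–2×10⁵
Monte-Carlo replicates, 1500–2000-protein simulations) are chosen so the
statistical tolerances above are decisive while the whole suite runs in
well under a minute per component.

## Known limitations

- The consistency rule's all-or-nothing handling of missingness discards
  proteins with a single dropout in a compared group; the
  minimum-ratio-count alternative is configurable but not the default.
- The analytic paired-rule null assumes independent ratio directions
  across pools; correlated technical effects would inflate it.
- Marker panels are fixed gene-symbol lists with aliases as separate
  entries; no identifier mapping is attempted, so quantification outputs
  using other nomenclature must be harmonised upstream.
- Venn reporting is counts/percentages only; graphical rendering is out
  of scope.
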