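# Methods

## The screening model

The package implements a multi-stage screen for candidate disease genes
in a small case-control exome cohort. The analysis starts from *called,
annotated* variants — alignment, variant calling and annotation are
upstream of this package — and proceeds:

1. **Rare damaging filter.** Keep variants with reference-population
   MAF strictly below `maf_threshold` (default 0.005, i.e. 0.5%) whose
   functional class is in the damaging set (splice-site, nonsense,
   frameshift, missense), whose ACMG class is in the keep set
   (pathogenic, likely pathogenic, VUS) and — for missense only — with at
   least `min_damaging_predictors` (default 2 of 3) in-silico damaging
   verdicts (SIFT / PolyPhen / MutationTaster). The MAF bound is strict
   (`<`) and the MAF column is interpreted as the maximum across
   reference panels; an empty MAF reads as 0 (a variant absent from all
   panels is rare). All of this is configurable.
2. **Per-variant Fisher association**, allele mode by default (alt vs
   ref allele counts; carrier mode available), one-sided toward case
   enrichment, significant at p < 0.05.
3. **Gene-level burden.** Carrier collapsing (carrier = ≥1 alt allele at
   ≥1 of the gene's variants; missing genotypes never count), one-sided
   Fisher on carrier counts, BH FDR across all genes entering the test
   (the post-filter gene universe), and the three-part pass rule
   described in the README. Criterion 2 is read *per variant* — some
   single variant must be hit in ≥3 cases — with a `per_gene`
   alternative (≥3 distinct gene carriers) behind the `hit_unit` switch,
   because either reading of "hit for at least one variant in three
   cases" is defensible. Criterion 1 is an OR of p and q.
4. **Over-representation** of the candidate union (genes of significant
   variants ∪ burden-significant genes) against GMT sets: exact
   hypergeometric upper tail, background defaulting to all genes
   annotated to any set (configurable), sets with zero overlap excluded
   from the BH family. The pathway terms whose member genes advance are
   a curatorial choice, so they are supplied explicitly (the pipeline
   falls back to all significant terms when none are given).
5. **Network prioritization.** Over an undirected edge list
   (deduplicated, self-loops dropped), each candidate is scored by the
   number of distinct known disease genes adjacent to it, per known-gene
   list, summed across lists. Weighted degree and betweenness are
   offered as alternatives; edge weights are otherwise ignored (an
   optional minimum-weight filter exists). The cut (`k` or `min_score`)
   is an explicit parameter — there is no principled default for how
   many genes to carry forward.
6. **Expression prioritization** across developmental stages (Carnegie
   S10–S16 by default): keep genes whose mean stage expression (or every
   stage, under `all_stages_above`) clears a threshold. No canonical
   numeric cutoff exists for this step, so the default threshold is the
   median of the per-gene stage means of the supplied matrix — "above
   the typical gene" — explicit and overridable. Values are used as
   provided; no inter-array normalization is attempted.

## Exact statistics

`fisher_exact_2x2` and `hypergeom_tail` are computed with exact integer
arithmetic (`math.comb`): with margins fixed, every table probability
shares the denominator C(N, k), so tails are integer sums divided once
at the end, and the two-sided rule "sum of probabilities ≤ P(observed)"
compares integers, making tie handling exact. Tests cross-check both
functions against an independent rational-enumeration oracle
(exhaustively for all Fisher tables with N ≤ 60 and all hypergeometric
configurations with N ≤ 40) and against the scipy implementations.
Results are memoized, which makes the repeated identical zero-control
tables of a burden scan essentially free. BH adjustment delegates to
statsmodels (`fdr_bh`) and returns q-values in input order.

Ties in every ranking are broken deterministically (p ascending, then
identifier; network score descending, then gene), so all outputs are
stable across runs. Degenerate inputs are defined rather than fatal: a
variant with all genotypes missing gets p = 1 with a warning; an empty
post-filter variant set empties all later stages but still produces a
valid report.

## The synthetic cohort generator

The generator's defaults are the study conditions of the target design:
39 cases and 100 controls; 1000 null genes and 5 planted risk genes, one
variant per gene; planted carrier probability 0.15 per case and 0 per
control; null carrier probability 0.01 in both groups; MAF drawn
uniformly from [0, 0.005); substitution weights 0.30 for C>T and 0.30
for G>A with the remaining ten single-base classes sharing 0.40 (the two
transitions jointly the majority, as observed in real rare-damaging
spectra); half the null variants annotated damaging, planted variants
always rare and damaging. Carriers are drawn per sample at the gene
level and assigned to one of the gene's variants uniformly at random —
the burden unit is the gene-level carrier and variant identity is
secondary. Carrier genotypes are heterozygous by default (`hom_alt_prob`
knob, default 0; rare variants at these frequencies are overwhelmingly
het) and missingness defaults to 0 (`missing_rate` knob; missing entries
never count as carriers, and the truth set records carrier counts as
realized in the final matrix).

A planted gene at case carrier probability 0.15 realizes ≥3 case
carriers in most draws (P ≈ 0.95 for Binomial(39, 0.15) ≥ 3), so the
"eligible" subset of planted genes — those whose best single variant is
hit in ≥3 cases with no control carrier — is the recovery oracle for the
burden criteria and the end-to-end cascade.

Matched resources share the config seed through a hierarchical stream
(one child stream for the cohort, one for the resources, so generating
resources never perturbs the cohort draw): a designated
cardiac-development gene set of 50 genes containing all planted genes
plus random null-only sets; two known-gene stand-in lists ("CHD", "PDA",
10 genes each) wired to planted genes with edge probability 0.5 vs 0.02
for null genes; and a gene × 7-stage expression matrix, gamma-distributed
baseline (shape 2, scale 1) with planted genes shifted up by ~10 units so
they clear the median-of-means threshold.

What the generator does **not** emulate: linkage disequilibrium,
population structure, relatedness, sequencing error, per-variant MAF
heterogeneity tied to carrier frequency, and realistic gene-length or
pathway-size distributions. Passing recovery tests therefore shows the
cascade's logic is correct under its own assumptions — independent
carriers, truthful annotations — not that the screen is well powered or
well calibrated on real exomes with those confounders.

## Problem sizes used in tests and the acceptance script

Null calibration and planted-gene recovery are checked over 200
simulated cohorts each (39/100, 1005 genes) in the test suite, with the
end-to-end pipeline recovery additionally exercised on 12 full synthetic
runs; the acceptance script uses 50 cohorts per property and exhaustive
oracle sweeps to N ≤ 40 (Fisher) and N ≤ 30 (hypergeometric). These
sizes give binomial Monte-Carlo error well below the asserted margins
(all bounds use 3 standard errors) while keeping a full run in the
tens of seconds on one CPU.

## Known limitations

- The burden test is plain carrier collapsing: no variant weights, no
  variance-component (SKAT-type) test, no permutation p-values, no
  covariate adjustment.
- The FDR family is the post-filter gene universe; filtering choices
  therefore change q-values (documented, inherent to the design).
- ACMG classes and predictor verdicts are taken from the annotation
  table as given; the package does not re-derive them.
- The ORA background defaults to the collection's own gene universe, not
  the exome; with small curated collections this can overstate
  enrichment and should be overridden with an explicit universe when one
  is available.
- Network scoring is first-order (direct neighbors only); genes two hops
  from every known gene score 0.
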