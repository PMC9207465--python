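# pdascreen

Rare-variant case-control gene prioritization for small exome cohorts,
built for congenital heart defect studies such as nonsyndromic patent
ductus arteriosus (PDA) — but applicable to any case-control design that
screens rare damaging variants and funnels candidate genes through
association, burden, pathway, network and developmental-expression
evidence.

## Who this is for

Groups that have sequenced a small patient cohort (tens of cases) against
a control panel and want a reproducible, scriptable version of the
familiar candidate-gene funnel: filter to rare damaging variants, test
each variant and each gene for case enrichment, then prioritize the
surviving genes with orthogonal evidence (gene-set over-representation,
protein-interaction connectivity to known disease genes, embryonic-heart
expression). Every stage is a plain function over typed containers, and a
synthetic cohort generator with *planted* risk genes lets you validate
the entire cascade against a known truth before touching real data.

## The statistics

**Per-variant association.** For each variant a 2×2 table of alt/ref
allele counts (or carrier/non-carrier samples) in cases vs controls is
tested with Fisher's exact test. The implementation uses exact integer
arithmetic — every tail probability is a ratio of sums of
binomial-coefficient products — so there is no continuity correction and
tied tables in the two-sided test are resolved exactly.

**Gene-level burden.** Variants are collapsed per gene: sample *i* is a
carrier of gene *g* if it holds ≥1 alternate allele at ≥1 of *g*'s
qualifying variants. With *a* case carriers among *n₁* cases and *c*
control carriers among *n₂* controls, the one-sided Fisher p-value is the
hypergeometric upper tail P(X ≥ a); q-values are Benjamini–Hochberg
across all tested genes. A gene is a **candidate** when simultaneously

1. p < 0.05 **or** q < 0.05,
2. at least one single variant is hit in ≥ 3 cases, and
3. no control sample carries the gene (configurable to a nonzero cap).

When c = 0 the upper tail collapses to the closed form
∏_{i=0}^{a−1} (n₁ − i)/(n₁ + n₂ − i): for a 39/100 cohort, 4 case
carriers give p ≈ 0.0055 (printed 0.006), 5 give 0.001, ≥6 give < 0.0005.

**Downstream prioritization.** Candidate genes (union of
Fisher-significant variant genes and burden-significant genes) are tested
for over-representation in GMT gene sets with the exact hypergeometric
tail (BH-adjusted, zero-overlap sets excluded from the family); genes of
selected pathway terms are then ranked by the number of known
disease-gene neighbors in a supplied interaction edge list; finally,
genes whose expression across Carnegie stages S10–S16 clears a threshold
form the final list.

## Worked example

One command simulates a 39-case / 100-control cohort with 1000 null
genes and 5 planted risk genes (case carrier probability 0.15, absent in
controls), writes all input files (VCF, sample sheet, annotation TSV,
GMT, edge list, expression TSV), runs the full cascade, and scores the
recovery:

```bash
pdascreen demo --seed 7 --out demo_out
```

prints (abridged):

```
{
  "eligible":           ["RISK001", "RISK002", "RISK003", "RISK004", "RISK005"],
  "eligible_recovered": ["RISK001", "RISK002", "RISK003", "RISK004", "RISK005"],
  "false_positives": [],
  "final_genes":        ["RISK001", "RISK002", "RISK003", "RISK004", "RISK005"]
}
recovered 5 / 5 eligible planted genes
```

"Eligible" are planted genes whose realized signal can satisfy the
burden criteria (best single variant hit in ≥3 cases, no control
carrier). The gene-level table `demo_out/results/burden.tsv` starts:

```
gene     case_mutation  case_normal  control_mutation  control_normal  p            p_rounded  q
RISK001  8              31           0                 100             2.18547e-05  0.000      0.00557
RISK002  8              31           0                 100             2.18547e-05  0.000      0.00557
RISK005  6              33           0                 100             3.63335e-04  0.000      0.06177
```

i.e. 8 of 39 cases and 0 of 100 controls carry RISK001, giving an exact
one-sided p of 2.2×10⁻⁵ (rendered 0.000 at 3 decimals) and a BH q of
0.0056 over the 1001 genes tested after filtering.

Each stage is also its own subcommand (`simulate`, `filter`, `assoc`,
`burden`, `ora`, `network`, `expression`) and `pdascreen run --config
pipeline.yaml` executes the whole cascade on your own files; all
artifacts are TSV/JSON in the output directory.

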