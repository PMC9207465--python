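"""Gene-level carrier collapsing and the three-part candidate-gene criteria.

Rare qualifying variants are collapsed per gene: a sample is a gene
carrier iff it holds at least one alt allele at at least one of the
gene's variants. Carrier counts feed a one-sided Fisher exact test of
case enrichment, BH-adjusted across all tested genes, and a gene is a
candidate when simultaneously (1) p or q is below alpha, (2) some single
variant is hit in at least `min_case_hits` cases, and (3) control
carriers do not exceed `max_control_carriers` (default zero: absent from
every control).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .cohort_io import CohortGenotypes, VariantRecord
from .stats import ContingencyTable2x2, bh_fdr, fisher_exact_2x2


@dataclass(frozen=True)
class GeneCollapse:
    """Per-gene collapsed counts before testing."""

    gene: str
    table: ContingencyTable2x2  # case carriers / case non / control carriers / control non
    n_variants_in_gene: int
    max_case_hits_single_variant: int
    n_case_carriers_gene: int  # distinct case carriers of the gene (any variant)


@dataclass(frozen=True)
class BurdenCriteria:
    alpha: float = 0.05
    min_case_hits: int = 3
    max_control_carriers: int = 0
    # 'per_variant': some single variant hit in >= min_case_hits cases
    # 'per_gene':    >= min_case_hits distinct case carriers of the gene
    hit_unit: Literal["per_variant", "per_gene"] = "per_variant"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_case_hits < 1:
            raise ValueError("min_case_hits must be >= 1")


@dataclass(frozen=True)
class GeneBurdenResult:
    gene: str
    table: ContingencyTable2x2
    p: float
    q: float
    n_variants_in_gene: int
    max_case_hits_single_variant: int
    passes: bool


def collapse_carriers(
    genotypes: CohortGenotypes, annotations: Sequence[VariantRecord]
) -> dict[str, GeneCollapse]:
    """Collapse variants to gene-level carrier contingency tables.

    Missing genotypes never count as carriers; a case carrying two of a
    gene's variants is one carrier. Also records, per gene, the largest
    number of cases sharing any single variant (drives criterion 2).
    """
    by_id = {r.variant_id: r for r in annotations}
    orphans = [v for v in genotypes.variant_ids if v not in by_id]
    if orphans:
        raise ValueError(f"variant(s) without gene mapping: {', '.join(orphans[:5])}")
    case_mask = genotypes.case_mask
    n_cases, n_controls = genotypes.n_cases, genotypes.n_controls
    gene_rows: dict[str, list[int]] = {}
    for i, vid in enumerate(genotypes.variant_ids):
        gene_rows.setdefault(by_id[vid].gene, []).append(i)
    out: dict[str, GeneCollapse] = {}
    for gene, rows in gene_rows.items():
        sub = genotypes.genotypes[rows, :] >= 1
        carrier = sub.any(axis=0)
        a = int(np.sum(carrier & case_mask))
        c = int(np.sum(carrier & ~case_mask))
        max_hits = int((sub & case_mask).sum(axis=1).max())
        out[gene] = GeneCollapse(
            gene=gene,
            table=ContingencyTable2x2(a, n_cases - a, c, n_controls - c),
            n_variants_in_gene=len(rows),
            max_case_hits_single_variant=max_hits,
            n_case_carriers_gene=a,
        )
    return out


def burden_test(
    collapsed: Mapping[str, GeneCollapse], criteria: BurdenCriteria = BurdenCriteria()
) -> list[GeneBurdenResult]:
    """Fisher (greater) per gene, BH across genes, three-part pass flag.

    Results are sorted by (p, gene) ascending.
    """
    if not collapsed:
        raise ValueError("no genes to test")
    genes = sorted(collapsed)
    pvals = [fisher_exact_2x2(collapsed[g].table, "greater") for g in genes]
    qvals = bh_fdr(pvals)
    results = []
    for g, p, q in zip(genes, pvals, qvals):
        col = collapsed[g]
        hits = (
            col.max_case_hits_single_variant
            if criteria.hit_unit == "per_variant"
            else col.n_case_carriers_gene
        )
        passes = (
            (p < criteria.alpha or q < criteria.alpha)
            and hits >= criteria.min_case_hits
            and col.table.c <= criteria.max_control_carriers
        )
        results.append(
            GeneBurdenResult(
                gene=g,
                table=col.table,
                p=p,
                q=float(q),
                n_variants_in_gene=col.n_variants_in_gene,
                max_case_hits_single_variant=col.max_case_hits_single_variant,
                passes=passes,
            )
        )
    return sorted(results, key=lambda r: (r.p, r.gene))


def top_burden_heatmap_data(
    results: Sequence[GeneBurdenResult],
    genotypes: CohortGenotypes,
    annotations: Sequence[VariantRecord],
    k: int = 10,
) -> tuple[list[str], list[str], np.ndarray]:
    """Top-k genes x case samples carried-variant counts, normalized per gene.

    Entries are the number of the gene's variants each case carries,
    divided by the gene's row maximum (all-zero rows stay zero). Returns
    (genes, case sample ids, matrix).
    """
    if not results:
        raise ValueError("no burden results")
    top = sorted(results, key=lambda r: (r.p, r.gene))[:k]
    by_id = {r.variant_id: r for r in annotations}
    case_mask = genotypes.case_mask
    case_samples = [s for s, m in zip(genotypes.sample_ids, case_mask) if m]
    gene_rows: dict[str, list[int]] = {}
    for i, vid in enumerate(genotypes.variant_ids):
        gene_rows.setdefault(by_id[vid].gene, []).append(i)
    mat = np.zeros((len(top), len(case_samples)))
    for gi, res in enumerate(top):
        rows = gene_rows.get(res.gene, [])
        if rows:
            counts = (genotypes.genotypes[rows][:, case_mask] >= 1).sum(axis=0).astype(float)
            peak = counts.max()
            mat[gi] = counts / peak if peak > 0 else counts
    return [r.gene for r in top], case_samples, mat
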