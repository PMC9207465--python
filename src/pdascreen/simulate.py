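"""Synthetic case-control exome cohorts with planted risk genes.

The generator emulates the statistical structure the downstream screen
assumes: a cohort of 39 cases and 100 controls, rare (MAF < 0.5%)
variants whose substitution spectrum is dominated by C>T and G>A, a
configurable number of planted risk genes whose carriers appear in cases
with probability `case_carrier_prob` and in controls with probability
`control_carrier_prob` (default 0 — absent from controls, the passing
condition of the burden criteria), and a background of null genes with
equal carrier probability in both groups. Matched gene-set, interaction
network and developmental-expression resources are generated so the
whole cascade can be exercised against a known truth set.

Carriers are simulated at the gene level and assigned to one of the
gene's variants uniformly at random — the burden unit is the gene-level
carrier, variant identity is secondary. Carrier genotypes default to
heterozygous; rare variants at these frequencies are overwhelmingly het.
One global seed drives a hierarchical stream (cohort / resources) so
generating resources never perturbs the cohort draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import (
    ACMG_CLASSES,
    MISSING,
    CohortGenotypes,
    VariantRecord,
)
from .enrichment import GeneSetCollection
from .expression import DEFAULT_STAGES, StageExpression


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _default_substitution_weights() -> dict[str, float]:
    # C>T and G>A jointly carry the majority of single-base substitutions;
    # the remaining ten classes share the rest evenly.
    weights = {"C>T": 0.30, "G>A": 0.30}
    others = [
        f"{r}>{a}"
        for r in "ACGT"
        for a in "ACGT"
        if r != a and f"{r}>{a}" not in weights
    ]
    weights.update({cls: 0.40 / len(others) for cls in others})
    return weights


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 39
    n_controls: int = 100
    n_null_genes: int = 1000
    n_planted_genes: int = 5
    variants_per_gene: int = 1
    case_carrier_prob: float = 0.15
    control_carrier_prob: float = 0.0
    null_carrier_prob: float = 0.01
    maf_range_rare: tuple[float, float] = (0.0, 0.005)
    substitution_weights: Mapping[str, float] = field(
        default_factory=_default_substitution_weights
    )
    damaging_fraction: float = 0.5
    hom_alt_prob: float = 0.0
    missing_rate: float = 0.0
    # resource knobs
    planted_known_edge_prob: float = 0.5
    null_known_edge_prob: float = 0.02
    n_known_per_list: int = 10
    cardiac_set_size: int = 50
    n_random_sets: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_planted_genes", "variants_per_gene"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_null_genes < 0:
            raise InvalidConfigError("n_null_genes must be >= 0")
        for name in (
            "case_carrier_prob",
            "control_carrier_prob",
            "null_carrier_prob",
            "damaging_fraction",
            "hom_alt_prob",
            "missing_rate",
            "planted_known_edge_prob",
            "null_known_edge_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.maf_range_rare
        if not (0.0 <= lo < hi <= 0.005):
            raise InvalidConfigError(
                f"maf_range_rare must satisfy 0 <= lo < hi <= 0.005, got {self.maf_range_rare}"
            )
        total = float(sum(self.substitution_weights.values()))
        if total <= 0:
            raise InvalidConfigError("substitution_weights must have positive mass")
        object.__setattr__(
            self,
            "substitution_weights",
            {k: v / total for k, v in self.substitution_weights.items()},
        )


@dataclass(frozen=True)
class TruthSet:
    """Recovery oracle: which genes carry planted signal and how strongly."""

    planted_genes: tuple[str, ...]
    case_carriers: dict[str, int]  # realized distinct case carriers per planted gene
    control_carriers: dict[str, int]
    best_variant_case_hits: dict[str, int]  # max cases sharing one variant


@dataclass
class PrioritizationResources:
    gene_sets: GeneSetCollection
    cardiac_term_id: str
    edges: list[tuple[str, str, float]]
    known_lists: dict[str, frozenset[str]]
    expression: StageExpression


_DAMAGING_FUNC = ("missense", "nonsense", "splice_site", "frameshift")
_DAMAGING_FUNC_P = (0.7, 0.1, 0.1, 0.1)  # missense dominates real exome screens
_BENIGN_FUNC = ("synonymous", "other")


def _draw_variant_annotation(
    rng: np.random.Generator,
    vid: str,
    gene: str,
    cfg: SimulationConfig,
    damaging: bool,
) -> VariantRecord:
    classes = list(cfg.substitution_weights)
    probs = np.array([cfg.substitution_weights[c] for c in classes])
    snv = classes[rng.choice(len(classes), p=probs)]
    ref, alt = snv.split(">")
    chrom = str(rng.integers(1, 23))
    pos = int(rng.integers(1, 250_000_000))
    maf = float(rng.uniform(*cfg.maf_range_rare))
    if damaging:
        func = _DAMAGING_FUNC[rng.choice(len(_DAMAGING_FUNC), p=_DAMAGING_FUNC_P)]
        verdicts = {t: "damaging" for t in ("sift", "polyphen", "mutationtaster")}
        acmg = str(rng.choice(["pathogenic", "likely_pathogenic", "VUS"], p=[0.1, 0.3, 0.6]))
    else:
        func = str(rng.choice(_BENIGN_FUNC, p=[0.8, 0.2]))
        verdicts = {t: "tolerated" for t in ("sift", "polyphen", "mutationtaster")}
        acmg = str(rng.choice(["likely_benign", "benign"], p=[0.5, 0.5]))
    return VariantRecord(
        variant_id=vid,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        func_class=func,
        snv_class=snv,
        maf=maf,
        predictor_verdicts=verdicts,
        acmg_class=acmg,
    )


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[CohortGenotypes, list[VariantRecord], TruthSet]:
    """Draw a cohort, its annotation table, and the planted-gene truth set.

    The matrix has (n_null_genes + n_planted_genes) * variants_per_gene
    rows and (n_cases + n_controls) columns; identical config (including
    seed) yields identical output. Planted-gene variants are always
    annotated rare and damaging; null-gene variants are damaging with
    probability `damaging_fraction`.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.seed).spawn(2)[0]))
    planted = [f"RISK{i + 1:03d}" for i in range(cfg.n_planted_genes)]
    nulls = [f"GENE{i + 1:05d}" for i in range(cfg.n_null_genes)]
    samples = [f"CASE{i + 1:03d}" for i in range(cfg.n_cases)] + [
        f"CTRL{i + 1:03d}" for i in range(cfg.n_controls)
    ]
    groups = ["case"] * cfg.n_cases + ["control"] * cfg.n_controls
    n_samples = cfg.n_cases + cfg.n_controls
    case_mask = np.array([g == "case" for g in groups])

    variant_ids: list[str] = []
    records: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for gene in planted + nulls:
        is_planted = gene in set(planted)
        p_case = cfg.case_carrier_prob if is_planted else cfg.null_carrier_prob
        p_ctrl = cfg.control_carrier_prob if is_planted else cfg.null_carrier_prob
        probs = np.where(case_mask, p_case, p_ctrl)
        carrier = rng.random(n_samples) < probs
        which = rng.integers(0, cfg.variants_per_gene, size=n_samples)
        dosage = np.where(rng.random(n_samples) < cfg.hom_alt_prob, 2, 1)
        gene_block = np.zeros((cfg.variants_per_gene, n_samples), dtype=np.int8)
        for s in np.nonzero(carrier)[0]:
            gene_block[which[s], s] = dosage[s]
        for j in range(cfg.variants_per_gene):
            vid = f"{gene}_v{j + 1}"
            variant_ids.append(vid)
            records.append(
                _draw_variant_annotation(
                    rng, vid, gene, cfg,
                    damaging=is_planted or bool(rng.random() < cfg.damaging_fraction),
                )
            )
            rows.append(gene_block[j])
    matrix = np.vstack(rows)
    if cfg.missing_rate > 0:
        matrix = np.where(rng.random(matrix.shape) < cfg.missing_rate, MISSING, matrix)

    cohort = CohortGenotypes(variant_ids, samples, groups, matrix)
    # realized truth from the final matrix, as downstream analysis sees it
    case_carriers: dict[str, int] = {}
    control_carriers: dict[str, int] = {}
    best_hits: dict[str, int] = {}
    for gi, gene in enumerate(planted):
        block = matrix[gi * cfg.variants_per_gene : (gi + 1) * cfg.variants_per_gene] >= 1
        carried = block.any(axis=0)
        case_carriers[gene] = int(np.sum(carried & case_mask))
        control_carriers[gene] = int(np.sum(carried & ~case_mask))
        best_hits[gene] = int((block & case_mask).sum(axis=1).max())
    truth = TruthSet(tuple(planted), case_carriers, control_carriers, best_hits)
    return cohort, records, truth


def generate_resources(cfg: SimulationConfig, truth: TruthSet) -> PrioritizationResources:
    """Matched gene sets, interaction network and expression matrix.

    The planted genes are all members of a designated cardiac-development
    gene set, are wired to known-gene stand-ins with elevated edge
    probability, and receive elevated expression across all stages, so a
    correct cascade recovers them end to end. Deterministic given the
    config seed; uses a stream independent of the cohort draw.
    """
    if not truth.planted_genes:
        raise ValueError("empty truth set")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.seed).spawn(2)[1]))
    planted = list(truth.planted_genes)
    nulls = [f"GENE{i + 1:05d}" for i in range(cfg.n_null_genes)]
    universe = planted + nulls

    # gene sets: one designated cardiac set holding every planted gene,
    # padded with null genes, plus random null-only sets
    cardiac_term = "CARDIAC_DEV"
    n_pad = max(0, min(cfg.cardiac_set_size, len(universe)) - len(planted))
    pad = list(rng.choice(nulls, size=n_pad, replace=False)) if n_pad and nulls else []
    sets: dict[str, tuple[str, frozenset[str]]] = {
        cardiac_term: ("cardiovascular development", frozenset(planted + pad))
    }
    for i in range(cfg.n_random_sets):
        size = int(rng.integers(20, 61))
        if nulls:
            members = frozenset(rng.choice(nulls, size=min(size, len(nulls)), replace=False))
            sets[f"SET{i + 1:03d}"] = (f"random process {i + 1}", members)
    collection = GeneSetCollection(sets, frozenset(universe))

    # known disease-gene stand-ins in two lists; planted genes attach to
    # them with much higher probability than null genes
    known_lists = {
        "CHD": frozenset(f"KNOWN_CHD_{i + 1:02d}" for i in range(cfg.n_known_per_list)),
        "PDA": frozenset(f"KNOWN_PDA_{i + 1:02d}" for i in range(cfg.n_known_per_list)),
    }
    known_all = sorted(known_lists["CHD"] | known_lists["PDA"])
    edges: list[tuple[str, str, float]] = []
    for gene in universe:
        p = cfg.planted_known_edge_prob if gene in truth.planted_genes else cfg.null_known_edge_prob
        hit = rng.random(len(known_all)) < p
        for ki in np.nonzero(hit)[0]:
            edges.append((gene, known_all[ki], float(np.round(rng.uniform(0.4, 1.0), 3))))
    for i, ka in enumerate(known_all):  # light scaffold among known genes
        for kb in known_all[i + 1 :]:
            if rng.random() < 0.1:
                edges.append((ka, kb, float(np.round(rng.uniform(0.4, 1.0), 3))))

    # expression: planted genes elevated across every stage
    base = rng.gamma(shape=2.0, scale=1.0, size=(len(universe), len(DEFAULT_STAGES)))
    values = pd.DataFrame(base, index=universe, columns=list(DEFAULT_STAGES))
    values.loc[planted] += 8.0 + rng.gamma(2.0, 1.0, size=(len(planted), len(DEFAULT_STAGES)))
    expression = StageExpression(values)

    return PrioritizationResources(
        gene_sets=collection,
        cardiac_term_id=cardiac_term,
        edges=edges,
        known_lists=known_lists,
        expression=expression,
    )
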