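"""Rare damaging-variant screen applied upstream of all statistics.

A variant survives when it is rare in reference populations (MAF strictly
below the threshold, default 0.5%) and damaging: its functional class is
in the damaging set (splice-site, nonsense, frameshift, missense by
default), missense additionally needs a minimum number of in-silico
damaging verdicts, and the ACMG class must be in the keep set
(pathogenic / likely pathogenic / VUS by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .cohort_io import ACMG_CLASSES, CohortGenotypes, FUNC_CLASSES, VariantRecord

logger = logging.getLogger(__name__)

DEFAULT_DAMAGING_CLASSES = frozenset({"splice_site", "nonsense", "frameshift", "missense"})
DEFAULT_ACMG_KEEP = frozenset({"pathogenic", "likely_pathogenic", "VUS"})


@dataclass(frozen=True)
class FilterConfig:
    maf_threshold: float = 0.005
    damaging_func_classes: frozenset = DEFAULT_DAMAGING_CLASSES
    min_damaging_predictors: int = 2  # applied to missense only
    acmg_keep: frozenset = DEFAULT_ACMG_KEEP

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold < 1.0:
            raise ValueError(f"maf_threshold must be in (0, 1), got {self.maf_threshold}")
        if self.min_damaging_predictors not in (0, 1, 2, 3):
            raise ValueError("min_damaging_predictors must be in 0..3")
        object.__setattr__(self, "damaging_func_classes", frozenset(self.damaging_func_classes))
        object.__setattr__(self, "acmg_keep", frozenset(self.acmg_keep))
        bad = self.damaging_func_classes - set(FUNC_CLASSES)
        if bad:
            raise ValueError(f"unknown functional class(es): {sorted(bad)}")
        bad = self.acmg_keep - set(ACMG_CLASSES)
        if bad:
            raise ValueError(f"unknown ACMG class(es): {sorted(bad)}")


def is_rare(variant: VariantRecord, cfg: FilterConfig = FilterConfig()) -> bool:
    """MAF strictly below the threshold (a variant at exactly 0.5% is common)."""
    return variant.maf < cfg.maf_threshold


def is_damaging(variant: VariantRecord, cfg: FilterConfig = FilterConfig()) -> bool:
    """Functional-class rule plus predictor-consensus rule plus ACMG keep set."""
    if variant.func_class not in cfg.damaging_func_classes:
        return False
    if (
        variant.func_class == "missense"
        and variant.n_damaging_predictors < cfg.min_damaging_predictors
    ):
        return False
    return variant.acmg_class in cfg.acmg_keep


def filter_rare_damaging(
    genotypes: CohortGenotypes,
    annotations: Sequence[VariantRecord],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[CohortGenotypes, list[VariantRecord]]:
    """Keep exactly the variants that are both rare and damaging.

    Order-preserving; genotype rows are subset in lockstep with the
    annotation list.
    """
    by_id = {r.variant_id: r for r in annotations}
    missing = [v for v in genotypes.variant_ids if v not in by_id]
    if missing:
        raise ValueError(f"no annotation for variant(s): {', '.join(missing[:5])}")
    keep_idx = [
        i
        for i, vid in enumerate(genotypes.variant_ids)
        if is_rare(by_id[vid], cfg) and is_damaging(by_id[vid], cfg)
    ]
    logger.info(
        "rare-damaging filter: retained %d / %d variants",
        len(keep_idx),
        len(genotypes.variant_ids),
    )
    kept = genotypes.subset_variants(keep_idx)
    return kept, [by_id[v] for v in kept.variant_ids]
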