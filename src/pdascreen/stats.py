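"""Exact association statistics for case-control carrier and allele counts.

The central primitive is Fisher's exact test on a 2x2 contingency table
(case-positive / case-negative / control-positive / control-negative),
computed with exact integer arithmetic: every table probability is a ratio
of binomial-coefficient products, so tail sums are accumulated as integers
and divided only once at the end. No continuity correction or asymptotic
approximation is used anywhere. Multiple-testing adjustment is
Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Literal, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

Alternative = Literal["greater", "two_sided"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts feeding one Fisher exact test.

    a: case-positive (e.g. case carriers), b: case-negative,
    c: control-positive, d: control-negative.  When built from a cohort,
    a + b equals the number of cases and c + d the number of controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationResult:
    """Per-unit (variant or gene) association outcome."""

    unit_id: str
    table: ContingencyTable2x2
    p: float
    q: float | None = None

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@lru_cache(maxsize=1 << 18)
def _fisher_p(a: int, b: int, c: int, d: int, alternative: str) -> float:
    # Margins fixed: row sums r1, r2 and first-column sum k. The number of
    # case-positives x ranges over the hypergeometric support; each table's
    # probability has the common denominator C(n, k), so only the integer
    # numerators C(r1, x) * C(r2, k - x) are compared and summed.
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, k - r2), min(r1, k)
    nums = [math.comb(r1, x) * math.comb(r2, k - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    if alternative == "greater":
        tail = sum(nums[a - lo :])
    elif alternative == "two_sided":
        tail = sum(m for m in nums if m <= obs)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return tail / math.comb(n, k)


def fisher_exact_2x2(table: ContingencyTable2x2, alternative: Alternative = "greater") -> float:
    """Exact Fisher p-value for a 2x2 table with fixed margins.

    ``greater`` is the upper hypergeometric tail P(X >= a) — enrichment of
    the positive outcome in cases; ``two_sided`` sums the probabilities of
    all tables no more probable than the observed one (exact tie handling
    via integer comparison).
    """
    if table.total == 0:
        raise ValueError("at least one count must be positive")
    return _fisher_p(table.a, table.b, table.c, table.d, alternative)


def format_p(p: float) -> str:
    """Render a p-value to 3 decimals, the convention of the result tables."""
    return f"{p:.3f}"


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q(i) = min_{j >= i}(p(j) * m / j) over the ascending order, capped at 1.
    """
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _carrier_table(dosages: np.ndarray, case_mask: np.ndarray) -> ContingencyTable2x2:
    carrier = dosages >= 1  # missing coded as -1, never a carrier
    a = int(np.sum(carrier & case_mask))
    c = int(np.sum(carrier & ~case_mask))
    return ContingencyTable2x2(a, int(case_mask.sum()) - a, c, int((~case_mask).sum()) - c)


def _allele_table(dosages: np.ndarray, case_mask: np.ndarray) -> ContingencyTable2x2:
    def counts(mask: np.ndarray) -> tuple[int, int]:
        g = dosages[mask]
        ok = g >= 0
        alt = int(g[ok].sum())
        return alt, 2 * int(ok.sum()) - alt

    alt_ca, ref_ca = counts(case_mask)
    alt_co, ref_co = counts(~case_mask)
    return ContingencyTable2x2(alt_ca, ref_ca, alt_co, ref_co)


def variant_association(
    genotypes: "CohortGenotypes",  # noqa: F821 - forward ref, see cohort_io
    mode: Literal["allele", "carrier"] = "allele",
) -> list[AssociationResult]:
    """Per-variant Fisher exact association between cases and controls.

    ``allele`` mode compares alt vs ref allele counts (the classic
    allele-frequency comparison); ``carrier`` mode compares carrier vs
    non-carrier sample counts. Variants with all genotypes missing get
    p = 1 with a warning. q-values are BH-adjusted across all variants.
    """
    case_mask = genotypes.case_mask
    if case_mask.sum() == 0 or (~case_mask).sum() == 0:
        raise ValueError("need at least one case and one control sample")
    build = _allele_table if mode == "allele" else _carrier_table
    results: list[AssociationResult] = []
    for i, vid in enumerate(genotypes.variant_ids):
        row = genotypes.genotypes[i]
        if np.all(row < 0):
            warnings.warn(f"variant {vid}: all genotypes missing, p set to 1")
            table = build(np.zeros_like(row), case_mask)
            p = 1.0
        else:
            table = build(row, case_mask)
            p = fisher_exact_2x2(table, "greater") if table.total > 0 else 1.0
        results.append(AssociationResult(vid, table, p))
    qvals = bh_fdr([r.p for r in results]) if results else []
    return [
        AssociationResult(r.unit_id, r.table, r.p, float(q))
        for r, q in zip(results, qvals)
    ]


def rank_units(results: Iterable[AssociationResult], k: int) -> list[AssociationResult]:
    """Top-k units by ascending p; ties broken lexicographically by unit id."""
    if k < 0:
        raise ValueError("k must be >= 0")
    ordered = sorted(results, key=lambda r: (r.p, r.unit_id))
    return ordered[:k]


def manhattan_points(results: Iterable[AssociationResult]) -> list[tuple[int, str, float]]:
    """(position index, unit id, -log10 p) triples for a Manhattan-style view."""
    out = []
    for i, r in enumerate(sorted(results, key=lambda r: (r.p, r.unit_id))):
        neglog = -math.log10(r.p) if r.p > 0 else math.inf
        out.append((i, r.unit_id, neglog))
    return out
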