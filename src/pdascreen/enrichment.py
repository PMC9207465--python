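"""Hypergeometric over-representation of candidate genes against gene sets.

A local, exact replacement for web-service enrichment: each GMT set is
tested with the upper hypergeometric tail P(X >= k) for drawing k set
members in a query of size n from a universe of size N containing K set
members, BH-adjusted across the sets actually tested (sets with zero
overlap are excluded from the family, the usual annotation-tool
convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .stats import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """term_id -> (term_name, member genes), with a background universe."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            # default background: every gene annotated to any set
            self.universe = frozenset().union(*(m for _, m in self.sets.values())) if self.sets else frozenset()
        clipped = {}
        for tid, (name, members) in self.sets.items():
            kept = frozenset(members) & self.universe
            if not kept:
                raise ValueError(f"gene set {tid} empty after universe restriction")
            clipped[tid] = (name, kept)
        self.sets = clipped


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # overlap
    K: int  # set size
    n: int  # query size
    N: int  # universe size
    p: float
    q: float


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """GMT: term_id <tab> description <tab> member genes..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
    return GeneSetCollection(sets, frozenset(universe) if universe else frozenset())


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(collection.sets):
            name, members = collection.sets[tid]
            fh.write("\t".join([tid, name, *sorted(members)]) + "\n")


@lru_cache(maxsize=1 << 16)
def _hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    hi = min(K, n)
    num = sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(k, hi + 1))
    return num / math.comb(N, n)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return _hypergeom_upper(k, K, n, N)


def run_ora(
    query: Iterable[str], collection: GeneSetCollection, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Over-representation of a query gene list against every set.

    Query genes outside the universe are dropped with a logged count; only
    sets with overlap >= 1 are tested and enter the BH family. Results are
    sorted by (p, term_id).
    """
    if not collection.universe:
        raise ValueError("empty gene universe")
    query_set = frozenset(query)
    dropped = query_set - collection.universe
    if dropped:
        logger.warning("run_ora: %d query gene(s) outside the universe dropped", len(dropped))
    query_set &= collection.universe
    n, N = len(query_set), len(collection.universe)
    tested = []
    for tid in sorted(collection.sets):
        name, members = collection.sets[tid]
        k = len(query_set & members)
        if k == 0:
            continue
        tested.append((tid, name, k, len(members)))
    if not tested:
        return []
    pvals = [hypergeom_tail(k, K, n, N) for _, _, k, K in tested]
    qvals = bh_fdr(pvals)
    results = [
        EnrichmentResult(tid, name, k, K, n, N, p, float(q))
        for (tid, name, k, K), p, q in zip(tested, pvals, qvals)
    ]
    return sorted(results, key=lambda r: (r.p, r.term_id))


def significant_terms(results: Sequence[EnrichmentResult], alpha: float = 0.05) -> list[str]:
    """Term ids significant at adjusted p < alpha."""
    return [r.term_id for r in results if r.q < alpha]


def select_pathway_genes(
    results: Sequence[EnrichmentResult],
    collection: GeneSetCollection,
    query: Iterable[str],
    selected_term_ids: Sequence[str],
) -> list[str]:
    """Union of (query ∩ set members) over the selected terms, sorted.

    Term selection is curatorial (e.g. cardiovascular-development terms),
    so the ids are supplied explicitly.
    """
    known = {r.term_id for r in results}
    unknown = [t for t in selected_term_ids if t not in known]
    if unknown:
        raise ValueError(f"unknown term id(s): {', '.join(unknown)}")
    query_set = frozenset(query)
    out: set[str] = set()
    for tid in selected_term_ids:
        out |= query_set & collection.sets[tid][1]
    return sorted(out)
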