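"""Candidate-gene prioritization by connectivity to known disease genes.

A local stand-in for interactive network tools: over a supplied
undirected interaction edge list, each candidate is scored by the number
of distinct known disease genes (per known-gene list, e.g. congenital
heart disease and ductus-specific lists) directly adjacent to it; the
combined score sums across lists. First-order degree to known genes is
the default operationalization of "degree of correlation"; weighted
degree and betweenness centrality are available as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx


@dataclass
class InteractionNetwork:
    """Undirected interaction graph plus named known-gene lists."""

    graph: nx.Graph
    known_lists: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        known_lists: Mapping[str, Iterable[str]] | None = None,
        min_weight: float | None = None,
    ) -> "InteractionNetwork":
        """Build from (gene_a, gene_b[, weight]) tuples.

        Self-loops are dropped and duplicate edges deduplicated regardless
        of orientation; an optional minimum edge weight filters low-
        confidence interactions.
        """
        g = nx.Graph()
        for edge in edges:
            a, b = edge[0], edge[1]
            w = float(edge[2]) if len(edge) > 2 else 1.0
            if a == b:
                continue
            if min_weight is not None and w < min_weight:
                continue
            g.add_edge(a, b, weight=w)
        lists = {
            name: frozenset(genes) for name, genes in (known_lists or {}).items()
        }
        return cls(g, lists)


@dataclass(frozen=True)
class NetworkScore:
    gene: str
    neighbor_counts: dict[str, int]  # per known list
    total_degree: int
    combined: float


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """TSV with header gene_a, gene_b[, weight]."""
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_weight = len(header) > 2
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            w = float(parts[2]) if has_weight and len(parts) > 2 else 1.0
            edges.append((parts[0], parts[1], w))
    return edges


def write_edge_list(edges: Sequence[tuple[str, str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w:g}\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """One gene symbol per line."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def score_connectivity(
    net: InteractionNetwork,
    candidates: Sequence[str],
    method: Literal["neighbors", "weighted_degree", "betweenness"] = "neighbors",
) -> list[NetworkScore]:
    """Score each candidate by direct connectivity to the known-gene lists.

    Default: per list, the count of distinct known genes adjacent to the
    candidate; combined = sum over lists. `weighted_degree` sums edge
    weights to known genes instead; `betweenness` scores candidates by
    betweenness centrality in the full graph (known-neighbor counts are
    still reported). Candidates absent from the network score 0.
    """
    if not candidates:
        raise ValueError("no candidate genes to score")
    g = net.graph
    betw = nx.betweenness_centrality(g) if method == "betweenness" else None
    scores = []
    for gene in candidates:
        neigh = set(g.neighbors(gene)) if gene in g else set()
        counts = {name: len(neigh & members) for name, members in net.known_lists.items()}
        if method == "neighbors":
            combined = float(sum(counts.values()))
        elif method == "weighted_degree":
            combined = sum(
                g[gene][nb]["weight"]
                for nb in neigh
                for name, members in net.known_lists.items()
                if nb in members
            )
        else:
            combined = betw.get(gene, 0.0)
        scores.append(
            NetworkScore(
                gene=gene,
                neighbor_counts=counts,
                total_degree=len(neigh),
                combined=float(combined),
            )
        )
    return scores


def prioritize_by_network(
    scores: Sequence[NetworkScore],
    k: int | None = None,
    min_score: float | None = None,
) -> list[str]:
    """Stable (combined desc, gene asc) ordering, cut at k or min_score."""
    if k is None and min_score is None:
        raise ValueError("one of k or min_score is required")
    if k is not None and k < 0:
        raise ValueError("k must be >= 0")
    ordered = sorted(scores, key=lambda s: (-s.combined, s.gene))
    if min_score is not None:
        ordered = [s for s in ordered if s.combined >= min_score]
    if k is not None:
        ordered = ordered[:k]
    return [s.gene for s in ordered]
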