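"""Final prioritization by expression across embryonic-heart developmental stages.

Candidate genes are kept when their expression across Carnegie stages
(S10-S16 by default) clears a threshold, either on the per-gene mean
(`mean_above`) or at every stage (`all_stages_above`). No numeric cutoff
is canonical for this step, so the default threshold is the median of the
matrix's per-gene means — "expressed above the typical gene" — and is
explicit and overridable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_STAGES = tuple(f"S{i}" for i in range(10, 17))


@dataclass
class StageExpression:
    """Gene x developmental-stage non-negative expression matrix."""

    values: pd.DataFrame  # index: gene symbols; columns: ordered stage labels

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene rows: {dupes[:5]}")
        if self.values.shape[1] < 1:
            raise ValueError("need at least one stage column")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)


def read_expression(path: str | Path) -> StageExpression:
    """TSV: gene column + one column per stage."""
    df = pd.read_csv(path, sep="\t").set_index("gene")
    return StageExpression(df.astype(float))


def write_expression(expr: StageExpression, path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.4f")


def expression_priority(
    expr: StageExpression,
    candidates: Sequence[str],
    rule: Literal["mean_above", "all_stages_above"] = "mean_above",
    threshold: float | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Keep candidates whose expression clears the threshold.

    Returns (final genes sorted by mean expression descending, per-gene
    summary frame with mean/min/max and the retained flag). Candidates
    absent from the matrix are dropped with a logged warning. With
    threshold=None the median of all genes' stage means is used.
    """
    if threshold is not None and threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold is None:
        threshold = float(expr.values.mean(axis=1).median())
    present = [g for g in candidates if g in expr.values.index]
    absent = sorted(set(candidates) - set(present))
    if absent:
        logger.warning(
            "expression_priority: %d candidate(s) absent from the matrix dropped: %s",
            len(absent), ", ".join(absent[:5]),
        )
    if not present:
        return [], pd.DataFrame(
            columns=["gene", "mean", "min", "max", "retained"]
        ).set_index("gene")
    sub = expr.values.loc[present]
    summary = pd.DataFrame(
        {
            "mean": sub.mean(axis=1),
            "min": sub.min(axis=1),
            "max": sub.max(axis=1),
        }
    )
    if rule == "mean_above":
        summary["retained"] = summary["mean"] >= threshold
    elif rule == "all_stages_above":
        summary["retained"] = (sub >= threshold).all(axis=1)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    summary.index.name = "gene"
    final = summary[summary["retained"]].sort_values(
        "mean", ascending=False, kind="stable"
    )
    if len(final):
        logger.info("expression_priority: top gene by mean expression is %s", final.index[0])
    return list(final.index), summary
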