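"""Fold-change expression screening and Venn partitioning.

Starting from a normalised genes x samples matrix (linear scale), the screen
computes per-gene fold changes between condition means, classifies genes as
up (> 2-fold, strict), down (< 0.5-fold, strict) or unchanged, and
partitions the up-genes of two contrasts — typically each disease-associated
condition versus the normal control, at the stricter > 4-fold threshold —
into exclusive and shared sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .synthsheet import ExpressionMatrix

logger = logging.getLogger(__name__)

UP_THRESHOLD = 2.0
DOWN_THRESHOLD = 0.5
VENN_THRESHOLD = 4.0


def fold_change(matrix: ExpressionMatrix, condition_a: str,
                condition_b: str) -> pd.Series:
    """Per-gene linear fold change: mean(a samples) / mean(b samples)."""
    a = matrix.values[matrix.samples_of(condition_a)].mean(axis=1)
    b = matrix.values[matrix.samples_of(condition_b)].mean(axis=1)
    fc = a / b
    fc.name = f"{condition_a}/{condition_b}"
    return fc


def classify(fc: float, up_threshold: float = UP_THRESHOLD,
             down_threshold: float = DOWN_THRESHOLD) -> str:
    """Label a fold change: 'up' if fc > up (strict), 'down' if fc < down
    (strict), else 'unchanged'.  A fold change exactly at a threshold is
    unchanged."""
    if fc <= 0:
        raise ValueError("fold change must be positive")
    if fc > up_threshold:
        return "up"
    if fc < down_threshold:
        return "down"
    return "unchanged"


def classify_series(fc: pd.Series, up_threshold: float = UP_THRESHOLD,
                    down_threshold: float = DOWN_THRESHOLD) -> pd.Series:
    if (fc <= 0).any():
        raise ValueError("fold changes must be positive")
    out = pd.Series("unchanged", index=fc.index, name="label")
    out[fc > up_threshold] = "up"
    out[fc < down_threshold] = "down"
    return out


@dataclass
class VennPartition:
    """Disjoint partition of two up-gene sets: exclusive and shared."""

    a_only: frozenset
    shared: frozenset
    b_only: frozenset

    def sizes(self) -> tuple[int, int, int]:
        return len(self.a_only), len(self.shared), len(self.b_only)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "a_only": sorted(self.a_only),
                    "shared": sorted(self.shared),
                    "b_only": sorted(self.b_only),
                },
                indent=2,
            )
        )


def venn_partition(up_in_a: set, up_in_b: set) -> VennPartition:
    """Split two gene sets into (A-only, shared, B-only)."""
    a, b = frozenset(up_in_a), frozenset(up_in_b)
    return VennPartition(a_only=a - b, shared=a & b, b_only=b - a)


@dataclass
class ScreenResult:
    """Full screen output: fold changes, labels, and the Venn partition."""

    table: pd.DataFrame  # per-gene FC and label per contrast
    partition: VennPartition
    contrasts: tuple[str, str]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="gene")


def screen(
    matrix: ExpressionMatrix,
    condition_a: str,
    condition_b: str,
    reference: str,
    up_threshold: float = UP_THRESHOLD,
    down_threshold: float = DOWN_THRESHOLD,
    venn_threshold: float = VENN_THRESHOLD,
) -> ScreenResult:
    """Two-contrast screen against a shared reference condition.

    Each of ``condition_a`` and ``condition_b`` is contrasted with
    ``reference``; genes are labelled up/down/unchanged at the 2 / 0.5
    thresholds, and the Venn partition is built from genes exceeding the
    stricter ``venn_threshold`` in each contrast.
    """
    fc_a = fold_change(matrix, condition_a, reference)
    fc_b = fold_change(matrix, condition_b, reference)
    table = pd.DataFrame(
        {
            f"fc_{condition_a}": fc_a,
            f"label_{condition_a}": classify_series(fc_a, up_threshold,
                                                    down_threshold),
            f"fc_{condition_b}": fc_b,
            f"label_{condition_b}": classify_series(fc_b, up_threshold,
                                                    down_threshold),
        }
    )
    up_a = set(fc_a.index[fc_a > venn_threshold])
    up_b = set(fc_b.index[fc_b > venn_threshold])
    part = venn_partition(up_a, up_b)
    logger.info(
        "screen %s/%s vs %s: partition sizes %s",
        condition_a, condition_b, reference, part.sizes(),
    )
    return ScreenResult(table=table, partition=part,
                        contrasts=(condition_a, condition_b))
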