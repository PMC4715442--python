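"""CES-D item bookkeeping and total/subscale scoring.

The CES-D has 20 items rated 0-3 by symptom frequency over the past week.
Sixteen "negative" items (depressive mood, somatic/retarded activities,
interpersonal relations) are scored as answered; the four positive-affect
items (4, 8, 12, 16) are reverse-scored (s -> 3 - s) so that higher always
means more distress.  Totals:

* Likert method: items scored 0-1-2-3; 20-item total in 0-60, 16-item
  (negative-only) total in 0-48.
* Binary method: each scored item recoded 1 if >= 1 else 0 (symptom
  present vs absent); totals in 0-20 and 0-16.

Binary recoding is applied after reverse-scoring by default; the
pre-reversal ordering is available via ``reverse_first=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEPRESSIVE_MOOD",
    "SOMATIC_RETARDED",
    "INTERPERSONAL",
    "POSITIVE_AFFECT",
    "NEGATIVE_ITEMS",
    "ALL_ITEMS",
    "SUBSCALES",
    "item_columns",
    "reverse_score",
    "likert_totals",
    "binary_totals",
    "score_matrix",
]

DEPRESSIVE_MOOD = frozenset({3, 6, 9, 10, 14, 17, 18})
SOMATIC_RETARDED = frozenset({1, 2, 5, 7, 11, 13, 20})
INTERPERSONAL = frozenset({15, 19})
POSITIVE_AFFECT = frozenset({4, 8, 12, 16})

NEGATIVE_ITEMS = frozenset(DEPRESSIVE_MOOD | SOMATIC_RETARDED | INTERPERSONAL)
ALL_ITEMS = tuple(range(1, 21))

SUBSCALES = {
    "depressive_mood": DEPRESSIVE_MOOD,
    "somatic_retarded": SOMATIC_RETARDED,
    "interpersonal": INTERPERSONAL,
    "positive_affect": POSITIVE_AFFECT,
}

assert len(NEGATIVE_ITEMS) == 16 and len(POSITIVE_AFFECT) == 4


def item_columns(items=ALL_ITEMS) -> list[str]:
    """Column names item_1 ... item_20 for the given item ids."""
    return [f"item_{i}" for i in items]


def reverse_score(raw: int) -> int:
    """Reverse a positive-affect item's raw code: s -> 3 - s."""
    if raw not in (0, 1, 2, 3):
        raise ValueError(f"item code must be in 0..3, got {raw}")
    return 3 - raw


@dataclass(frozen=True)
class ScoredRow:
    """All totals for one respondent (after reverse-scoring)."""

    total_20: int
    total_16: int
    binary_total_20: int
    binary_total_16: int
    subscale_totals: dict[str, int]


def _scored_items(raw_row: dict[int, int]) -> dict[int, int]:
    scored = {}
    for i in ALL_ITEMS:
        v = raw_row[i]
        if v not in (0, 1, 2, 3):
            raise ValueError(f"item_{i}: code must be in 0..3, got {v}")
        scored[i] = reverse_score(v) if i in POSITIVE_AFFECT else v
    return scored


def likert_totals(raw_row: dict[int, int]) -> ScoredRow:
    """Score one row of 20 raw item codes under both methods.

    ``raw_row`` maps item id (1-20) to the raw 0-3 code; positive items are
    reverse-scored here.  Returns Likert and binary totals plus the four
    subscale (Likert) totals.
    """
    scored = _scored_items(raw_row)
    binary = {i: (1 if s >= 1 else 0) for i, s in scored.items()}
    return ScoredRow(
        total_20=sum(scored.values()),
        total_16=sum(scored[i] for i in NEGATIVE_ITEMS),
        binary_total_20=sum(binary.values()),
        binary_total_16=sum(binary[i] for i in NEGATIVE_ITEMS),
        subscale_totals={
            name: sum(scored[i] for i in ids) for name, ids in SUBSCALES.items()
        },
    )


def binary_totals(
    raw_row: dict[int, int], reverse_first: bool = True
) -> tuple[int, int]:
    """Binary (0-1-1-1) totals for one row: (20-item, 16-item).

    With ``reverse_first`` (default) positive items are reverse-scored
    before binarization; otherwise the raw code is binarized directly.
    The 16-item total is unaffected by the choice.
    """
    if reverse_first:
        scored = _scored_items(raw_row)
    else:
        scored = {i: raw_row[i] for i in ALL_ITEMS}
        for i, v in scored.items():
            if v not in (0, 1, 2, 3):
                raise ValueError(f"item_{i}: code must be in 0..3, got {v}")
    binary = {i: (1 if s >= 1 else 0) for i, s in scored.items()}
    return (sum(binary.values()), sum(binary[i] for i in NEGATIVE_ITEMS))


def score_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scoring of a response matrix.

    Expects columns ``item_1`` ... ``item_20`` with integer codes 0-3 and
    no missing values (exclusions are applied upstream).  Returns a copy of
    the input frame with columns ``total_20``, ``total_16``,
    ``binary_total_20``, ``binary_total_16`` and one column per subscale.
    """
    cols = item_columns()
    raw = df[cols].to_numpy(dtype=float)
    if np.isnan(raw).any():
        raise ValueError("missing item responses; apply exclusions first")
    if not np.isin(raw, [0, 1, 2, 3]).all():
        raise ValueError("item codes outside 0..3")
    raw = raw.astype(np.int64)

    scored = raw.copy()
    pos_idx = [i - 1 for i in sorted(POSITIVE_AFFECT)]
    scored[:, pos_idx] = 3 - scored[:, pos_idx]
    binary = (scored >= 1).astype(np.int64)

    neg_idx = [i - 1 for i in sorted(NEGATIVE_ITEMS)]
    out = df.copy()
    out["total_20"] = scored.sum(axis=1)
    out["total_16"] = scored[:, neg_idx].sum(axis=1)
    out["binary_total_20"] = binary.sum(axis=1)
    out["binary_total_16"] = binary[:, neg_idx].sum(axis=1)
    for name, ids in SUBSCALES.items():
        idx = [i - 1 for i in sorted(ids)]
        out[name] = scored[:, idx].sum(axis=1)
    return out
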