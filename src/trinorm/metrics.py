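"""Per-item and aggregate normalization metrics.

The character and word stages record a Levenshtein distance per item
(original vs character-normalized, character-normalized vs word-normalized)
as a measure of how much each string changed.  No distance is tracked at
the phrase stage, where benign word-order changes would produce large and
meaningless scores.  Split datasets additionally record, once per original
item, the split phrase count and the phrase validity rate (valid segments /
split phrase count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
import pandas as pd


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert / delete / substitute) between a and b."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class ItemMetrics:
    """Per-original-item metric record."""

    char_distance: int = 0
    word_distance: int = 0
    split_phrase_count: int = 1
    phrase_validity_rate: float = 0.0
    protected: bool = False  # item had a protected (URL) prefix

    def __post_init__(self) -> None:
        if self.split_phrase_count < 1:
            raise ValueError("split_phrase_count must be >= 1")
        if not 0.0 <= self.phrase_validity_rate <= 1.0:
            raise ValueError("phrase_validity_rate must be in [0, 1]")
        if min(self.char_distance, self.word_distance) < 0:
            raise ValueError("distances must be >= 0")


def stage_validity(results: Sequence) -> float:
    """Fraction of items entering a stage that passed its validation.

    Accepts any sequence of objects with a boolean ``valid`` attribute (or
    of plain booleans).  Stage gating means the denominator is the number of
    items that entered *this* stage, not the whole dataset.
    """
    if len(results) == 0:
        raise ValueError("cannot compute a validity rate over zero items")
    flags = [bool(getattr(r, "valid", r)) for r in results]
    return sum(flags) / len(flags)


_METRIC_FIELDS = (
    "char_distance",
    "word_distance",
    "split_phrase_count",
    "phrase_validity_rate",
)


def summarize(items: Sequence[ItemMetrics], exclude_protected: bool = False) -> pd.DataFrame:
    """Aggregate per-item metrics: means, standard deviations, counts.

    Returns a DataFrame indexed by metric with columns ``mean``, ``sd_pop``
    (population standard deviation), ``sd_sample`` and ``n``.  With
    ``exclude_protected`` the protected-prefix (URL) items are dropped
    first, mirroring the URL-free view of a summary.
    """
    if exclude_protected:
        items = [m for m in items if not m.protected]
    if len(items) == 0:
        raise ValueError("no items to summarize (empty input or all items excluded)")
    rows = {}
    for name in _METRIC_FIELDS:
        values = np.array([getattr(m, name) for m in items], dtype=float)
        rows[name] = {
            "mean": values.mean(),
            "sd_pop": values.std(ddof=0),
            "sd_sample": values.std(ddof=1) if len(values) > 1 else 0.0,
            "n": len(values),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def distance_histogram(items: Sequence[ItemMetrics], which: str = "char_distance") -> pd.Series:
    """Frequency distribution of a distance metric, indexed by score."""
    if which not in _METRIC_FIELDS:
        raise ValueError(f"unknown metric {which!r}")
    values = pd.Series([getattr(m, which) for m in items])
    return values.value_counts().sort_index()


def format_summary(summary: pd.DataFrame) -> str:
    """Human-readable log block for a metrics summary table."""
    lines = ["metric summary:"]
    for name, row in summary.iterrows():
        lines.append(
            f"  {name}: mean={row['mean']:.4g} sd_pop={row['sd_pop']:.4g} "
            f"sd_sample={row['sd_sample']:.4g} n={int(row['n'])}"
        )
    return "\n".join(lines)
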