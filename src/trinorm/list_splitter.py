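"""Splitting list-like data-location items into atomic segments.

Curated data-location strings frequently pack several references into one
item ("Fig. 2A,B,C, Fig. 6."), which no finite set of phrase patterns could
match.  This accessory stage runs between word and phrase normalization for
list-like datasets and rewrites each item into individually normalizable
segments, with bookkeeping (original index, split index) so segments can be
traced back to their source row.

The splitting grammar:

* elements are separated by commas, semicolons, the standalone word "and"
  and "&" (a comma directly between two digits is numeric punctuation, not
  a separator);
* an element ending in a reference token (a number, optionally with a
  letter suffix like "2a"; an S-number like "s2"; or a PDB-style id)
  consists of a *head* (the words before it) and that reference; the head
  becomes the current head and distributes over following bare references;
* a bare single letter attaches to the current head and number ("2a", "b",
  "c" -> "fig. 2a", "fig. 2b", "fig. 2c"), lowercased;
* an element with no trailing reference stands on its own and resets the
  head;
* items with a protected prefix (URLs) are never split;
* trailing punctuation is stripped from each segment.

Range references ("Figs. 1-4") are NOT expanded into enumerations; such
items simply pass through for review.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .metrics import ItemMetrics
from .tokenizer import is_protected

#: comma/semicolon (not inside a number), standalone "and", or "&"
_SEPARATOR_RE = re.compile(r"\s*(?:;|,(?!(?<=\d,)\d)|\band\b|&)\s*", re.IGNORECASE)
#: number with optional single letter suffix, optional trailing period
_NUM_REF_RE = re.compile(r"(\d+)([A-Za-z])?\.?")
#: S-numbers ("S2") and PDB-style four-character ids
_OTHER_REF_RE = re.compile(r"[Ss]\d+\.?|\d[A-Za-z0-9]{3}\.?")
#: a bare letter element, e.g. the "B" of "2A,B,C"
_LETTER_RE = re.compile(r"([A-Za-z])\.?")

_TRAILING_PUNCT = " .,;:"


@dataclass(frozen=True)
class Segment:
    """One post-split sub-item, traceable to its source data item."""

    text: str
    original_index: int
    split_index: int


def split(item: str, protected_prefixes: Sequence[str] = ()) -> list[str]:
    """Split one data item into segment strings (an unsplittable item
    returns itself as its only segment)."""
    stripped = item.strip()
    if not stripped:
        return [item]
    if is_protected(stripped, protected_prefixes):
        return [stripped]

    segments: list[str] = []
    head: str | None = None
    number: str | None = None
    for element in _SEPARATOR_RE.split(stripped):
        element = element.strip(" ")
        if not element:
            continue
        words = element.split()
        last = words[-1]
        num_match = _NUM_REF_RE.fullmatch(last)
        other_match = _OTHER_REF_RE.fullmatch(last)
        letter_match = _LETTER_RE.fullmatch(element)
        if num_match or other_match:
            if len(words) > 1:
                head = " ".join(words[:-1])
            if num_match:
                number, letter = num_match.group(1), num_match.group(2)
                ref = number + (letter.lower() if letter else "")
            else:
                number = None
                ref = last.rstrip(".").lower()
            segments.append(f"{head} {ref}" if head else ref)
        elif letter_match and head and number:
            segments.append(f"{head} {number}{letter_match.group(1).lower()}")
        else:
            segments.append(element)
            head = None
            number = None

    segments = [s.strip(_TRAILING_PUNCT) for s in segments]
    segments = [s for s in segments if s]
    return segments or [stripped]


def split_items(
    items: Sequence[str], protected_prefixes: Sequence[str] = ()
) -> list[Segment]:
    """Split every item, assigning original and split indices."""
    out: list[Segment] = []
    for original_index, item in enumerate(items):
        for split_index, text in enumerate(split(item, protected_prefixes)):
            out.append(Segment(text=text, original_index=original_index,
                               split_index=split_index))
    return out


def explode_rows(
    segments: Sequence[Segment],
    metrics: dict[int, ItemMetrics] | None = None,
) -> pd.DataFrame:
    """One output row per segment; per-original metrics recorded exactly once.

    Metric columns (split phrase count, validity rate, distances) are
    populated only on each item's first segment row (split_index 0) so that
    corpus means and frequency distributions are not skewed by the row-count
    increase that splitting causes.
    """
    rows = []
    for seg in segments:
        row: dict[str, object] = {
            "original_index": seg.original_index,
            "split_index": seg.split_index,
            "segment": seg.text,
        }
        if metrics is not None and seg.split_index == 0:
            m = metrics.get(seg.original_index)
            if m is not None:
                row.update(
                    char_distance=m.char_distance,
                    word_distance=m.word_distance,
                    split_phrase_count=m.split_phrase_count,
                    phrase_validity_rate=m.phrase_validity_rate,
                )
        rows.append(row)
    columns = ["original_index", "split_index", "segment"]
    if metrics is not None:
        columns += ["char_distance", "word_distance", "split_phrase_count",
                    "phrase_validity_rate"]
    return pd.DataFrame(rows, columns=columns)
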