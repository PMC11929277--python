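"""Delimiter-preserving tokenization of free-text data items.

A *word* is a maximal run of non-delimiter characters; everything between
words (and before the first / after the last word) is a *delimiter run*.
Tokens remember the delimiter runs on both sides so that a data item can be
reassembled byte-for-byte after individual words are replaced or removed.

Two practical wrinkles are handled here rather than downstream:

* a ``.`` or ``,`` sandwiched directly between two digits is part of a
  number ("29.8", "11,782") and never acts as a delimiter;
* data items starting with a *protected prefix* (typically a URL scheme +
  host) are opaque: they tokenize as a single word so that slashes, colons
  and dots inside the URL are never treated as structure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

#: Default separator characters: whitespace, hyphen and common punctuation.
DEFAULT_DELIMITERS: frozenset[str] = frozenset(" \t-,.:;()[]/=")


@dataclass(frozen=True)
class Token:
    """One word of a data item plus its surrounding delimiter runs.

    ``left_delim`` is the delimiter run between the previous word and this
    one (empty string at start of item); ``right_delim`` the run up to the
    next word (empty at end of item).  Adjacent tokens share the run:
    ``tokens[i].right_delim == tokens[i + 1].left_delim``.
    """

    text: str
    start: int
    left_delim: str
    right_delim: str


def extract_chars(item: str) -> list[tuple[str, int]]:
    """Count each character of *item*, preserving first-occurrence order."""
    counts = Counter(item)
    seen: dict[str, int] = {}
    for ch in item:
        if ch not in seen:
            seen[ch] = counts[ch]
    return list(seen.items())


def _is_delimiter(item: str, i: int, delimiters: frozenset[str] | set[str]) -> bool:
    ch = item[i]
    if ch not in delimiters:
        return False
    if ch in ".," and 0 < i < len(item) - 1:
        # numeric punctuation: keep "29.8" and "11,782" whole
        if item[i - 1].isdigit() and item[i + 1].isdigit():
            return False
    return True


def is_protected(item: str, protected_prefixes: Sequence[str]) -> bool:
    """True when *item* starts with a protected (opaque) prefix such as a URL."""
    return any(prefix and item.startswith(prefix) for prefix in protected_prefixes)


def split_words(
    item: str,
    delimiters: Iterable[str] = DEFAULT_DELIMITERS,
    protected_prefixes: Sequence[str] = (),
) -> list[Token]:
    """Split *item* into :class:`Token` objects.

    Maximal runs of delimiter characters form a single delimiter run.  An
    item matching a protected prefix is returned as one opaque token.  A
    string containing no word characters yields an empty list.
    """
    if not item:
        return []
    if is_protected(item, protected_prefixes):
        return [Token(text=item, start=0, left_delim="", right_delim="")]
    delimiters = frozenset(delimiters)

    # alternating maximal runs of (is_word, start, text)
    runs: list[tuple[bool, int, str]] = []
    i = 0
    n = len(item)
    while i < n:
        is_delim = _is_delimiter(item, i, delimiters)
        j = i
        while j < n and _is_delimiter(item, j, delimiters) == is_delim:
            j += 1
        runs.append((not is_delim, i, item[i:j]))
        i = j

    tokens: list[Token] = []
    for k, (is_word, start, text) in enumerate(runs):
        if not is_word:
            continue
        left = runs[k - 1][2] if k > 0 else ""
        right = runs[k + 1][2] if k + 1 < len(runs) else ""
        tokens.append(Token(text=text, start=start, left_delim=left, right_delim=right))
    return tokens


def rejoin(tokens: Sequence[Token]) -> str:
    """Reassemble a data item from its tokens (inverse of :func:`split_words`)."""
    if not tokens:
        return ""
    parts = [tokens[0].left_delim]
    for tok in tokens:
        parts.append(tok.text)
        parts.append(tok.right_delim)
    return "".join(parts)
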