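"""Independent test oracles, coded separately from the package internals."""

from __future__ import annotations


def dp_levenshtein(a: str, b: str) -> int:
    """Full dynamic-programming edit-distance matrix (unit costs).

    Deliberately naive O(len(a) * len(b)) implementation used only to
    cross-check the package's distance routine.
    """
    n, m = len(a), len(b)
    row = list(range(m + 1))
    for i in range(1, n + 1):
        prev_diag = row[0]
        row[0] = i
        for j in range(1, m + 1):
            cur = row[j]
            cost = 0 if a[i - 1] == b[j - 1] else 1
            row[j] = min(row[j] + 1, row[j - 1] + 1, prev_diag + cost)
            prev_diag = cur
    return row[m]
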