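"""Review/reference rule files and the phrase-type ruleset.

The normalization workflow is deliberately user-dependent.  On every run a
stage collects the distinct text units (characters or words) of the dataset
and writes the undecided ones to a *review* TSV; the user records an action
decision for a unit by filling exactly one of four action columns
(``replace_with``, ``remove``, ``invalidate``, ``allow``); on the next run
decided rows migrate to the *reference* TSV, the persistent rule bank that
is actually applied.

Phrase rules live in a separate phrase-type ruleset TSV, mapping a named
category sequence (e.g. ``[number(0)] [range_indicator(1)] [number(2)]
[unit(3)]``) to a validity verdict and a standard-form template.

File dialect: UTF-8 TSV with a header row and no quoting; literal tabs are
never allowed inside fields (context samples replace them with spaces).
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .tokenizer import DEFAULT_DELIMITERS, extract_chars, split_words

logger = logging.getLogger(__name__)

CONTEXT_CAP = 300

#: Characters treated as valid by default at the character stage: lowercase
#: letters, digits and a small set of basic punctuation.
DEFAULT_VALID_CHARS: frozenset[str] = frozenset(
    "abcdefghijklmnopqrstuvwxyz0123456789 .,-:;()/"
)


class MalformedRuleError(ValueError):
    """A rule row or pattern row violates the file contract."""


class Action(enum.Enum):
    REPLACE_WITH = "replace_with"
    REMOVE = "remove"
    INVALIDATE = "invalidate"
    ALLOW = "allow"
    UNDECIDED = "undecided"


@dataclass
class UnitRule:
    """One character or word with the user's action decision."""

    unit: str
    context: str = ""
    count: int = 1
    action: Action = Action.UNDECIDED
    value: str | None = None  # replacement text when action is REPLACE_WITH
    category: str | None = None  # words only

    def __post_init__(self) -> None:
        if self.count < 1:
            raise MalformedRuleError(f"count must be >= 1 for unit {self.unit!r}")
        if self.action is Action.REPLACE_WITH and not self.value:
            raise MalformedRuleError(
                f"replace_with for unit {self.unit!r} has no replacement text; "
                "use the remove action to delete a unit"
            )
        if self.action is not Action.REPLACE_WITH:
            self.value = None
        self.context = self.context.replace("\t", " ")[:CONTEXT_CAP]

    @property
    def decided(self) -> bool:
        return self.action is not Action.UNDECIDED


class RuleSet:
    """An ordered mapping unit -> :class:`UnitRule` (a review or reference table).

    ``kind`` is ``"char"`` or ``"word"``; word tables carry the extra
    ``category`` column.
    """

    def __init__(self, rules: Iterable[UnitRule] = (), kind: str = "char") -> None:
        if kind not in ("char", "word"):
            raise ValueError(f"kind must be 'char' or 'word', got {kind!r}")
        self.kind = kind
        self._rules: dict[str, UnitRule] = {}
        for rule in rules:
            self.add(rule)

    def add(self, rule: UnitRule) -> None:
        self._rules[rule.unit] = rule

    def __contains__(self, unit: str) -> bool:
        return unit in self._rules

    def __len__(self) -> int:
        return len(self._rules)

    def __iter__(self):
        return iter(self._rules.values())

    def get(self, unit: str) -> UnitRule | None:
        return self._rules.get(unit)

    def pop(self, unit: str) -> UnitRule:
        return self._rules.pop(unit)

    def units(self) -> list[str]:
        return list(self._rules)

    def by_action(self, action: Action) -> dict[str, UnitRule]:
        return {u: r for u, r in self._rules.items() if r.action is action}

    def replacements(self) -> dict[str, str]:
        return {u: r.value or "" for u, r in self.by_action(Action.REPLACE_WITH).items()}

    def removed(self) -> set[str]:
        return set(self.by_action(Action.REMOVE))

    def invalidated(self) -> set[str]:
        return set(self.by_action(Action.INVALIDATE))

    def allowed(self) -> set[str]:
        return set(self.by_action(Action.ALLOW))

    def categories(self) -> dict[str, str]:
        return {u: r.category for u, r in self._rules.items() if r.category}

    def copy(self) -> "RuleSet":
        return RuleSet((replace(r) for r in self), kind=self.kind)

    # ---------------------------------------------------------------- I/O

    _BASE_COLUMNS = ("unit", "context", "count", "replace_with", "remove", "invalidate", "allow")

    @property
    def columns(self) -> tuple[str, ...]:
        if self.kind == "word":
            return self._BASE_COLUMNS + ("category",)
        return self._BASE_COLUMNS

    def to_tsv(self, path: str | Path) -> None:
        lines = ["\t".join(self.columns)]
        for r in self:
            cells = {
                "unit": r.unit,
                "context": r.context,
                "count": str(r.count),
                "replace_with": r.value or "",
                "remove": "x" if r.action is Action.REMOVE else "",
                "invalidate": "x" if r.action is Action.INVALIDATE else "",
                "allow": "x" if r.action is Action.ALLOW else "",
                "category": r.category or "",
            }
            lines.append("\t".join(cells[c] for c in self.columns))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "RuleSet":
        path = Path(path)
        ruleset = cls(kind=kind)
        if not path.exists():
            return ruleset
        text = path.read_text(encoding="utf-8")
        lines = text.splitlines()
        if not lines:
            return ruleset
        header = lines[0].split("\t")
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            cells = dict(zip(header, line.split("\t")))
            ruleset.add(_rule_from_cells(cells, path, lineno))
        return ruleset


def _rule_from_cells(cells: dict[str, str], path: Path, lineno: int) -> UnitRule:
    unit = cells.get("unit", "")
    populated = [
        name
        for name in ("replace_with", "remove", "invalidate", "allow")
        if cells.get(name, "").strip()
    ]
    if len(populated) > 1:
        raise MalformedRuleError(
            f"{path}:{lineno}: unit {unit!r} has multiple action decisions: "
            + ", ".join(populated)
        )
    action = Action(populated[0]) if populated else Action.UNDECIDED
    count_text = cells.get("count", "1").strip() or "1"
    try:
        count = int(count_text)
    except ValueError as exc:
        raise MalformedRuleError(f"{path}:{lineno}: bad count {count_text!r}") from exc
    return UnitRule(
        unit=unit,
        context=cells.get("context", ""),
        count=count,
        action=action,
        value=cells.get("replace_with", "").strip() or None,
        category=cells.get("category", "").strip() or None,
    )


# ------------------------------------------------------------- unit survey


def collect_units(
    items: Sequence[str],
    stage: str,
    delimiters: Iterable[str] = DEFAULT_DELIMITERS,
    protected_prefixes: Sequence[str] = (),
) -> list[tuple[str, str, int]]:
    """Survey a dataset for distinct units: returns (unit, context_sample, count).

    ``stage`` is ``"char"`` or ``"word"``.  Counts are total occurrences
    across all data-item instances; the context sample concatenates distinct
    containing items in dataset order, " | "-separated, capped at 300 chars.
    """
    counts: dict[str, int] = {}
    contexts: dict[str, list[str]] = {}
    for item in items:
        if stage == "char":
            units = extract_chars(item)
        elif stage == "word":
            units = [(tok.text, 1) for tok in split_words(item, delimiters, protected_prefixes)]
            merged: dict[str, int] = {}
            for text, k in units:
                merged[text] = merged.get(text, 0) + k
            units = list(merged.items())
        else:
            raise ValueError(f"stage must be 'char' or 'word', got {stage!r}")
        for unit, k in units:
            counts[unit] = counts.get(unit, 0) + k
            sample = contexts.setdefault(unit, [])
            if item not in sample and len(" | ".join(sample)) < CONTEXT_CAP:
                sample.append(item)
    return [
        (unit, " | ".join(contexts[unit])[:CONTEXT_CAP], counts[unit]) for unit in counts
    ]


def build_review(
    units: Sequence[tuple[str, str, int]],
    review: RuleSet,
    reference: RuleSet,
    default_valid: frozenset[str] | set[str] | None = None,
) -> RuleSet:
    """Add a review row for every surveyed unit not yet known.

    ``default_valid`` is consulted only at the character stage: units in the
    always-valid default set never enter review.  Units already present in
    review or reference are left untouched (reference rows in particular are
    never modified here).
    """
    updated = review.copy()
    defaults = default_valid if review.kind == "char" and default_valid is not None else frozenset()
    for unit, context, count in units:
        if unit in defaults or unit in updated or unit in reference:
            continue
        updated.add(UnitRule(unit=unit, context=context, count=count))
    return updated


def migrate_decided(review: RuleSet, reference: RuleSet) -> tuple[RuleSet, RuleSet]:
    """Move decided review rows into the reference rule bank.

    Undecided rows stay in review.  A unit present in both tables is a
    conflict: the reference rule wins and the review row is dropped with a
    warning.  Idempotent: migrating twice equals migrating once.
    """
    new_review = RuleSet(kind=review.kind)
    new_reference = reference.copy()
    for rule in review:
        if rule.unit in new_reference:
            logger.warning(
                "unit %r present in both review and reference; keeping reference rule",
                rule.unit,
            )
            continue
        if rule.decided:
            new_reference.add(replace(rule))
        else:
            new_review.add(replace(rule))
    return new_review, new_reference


def mass_allow(
    review: RuleSet,
    reference: RuleSet,
    pattern: str,
    category: str | None = None,
) -> tuple[RuleSet, RuleSet]:
    """Allow every undecided review unit matching *pattern* in one sweep.

    Mirrors bulk rule-setting for regular unit families (e.g. PDB-style
    identifiers or plain numbers): matching rows become allow rules, with an
    optional category, and migrate straight to the reference table.
    """
    rx = re.compile(pattern)
    new_review = RuleSet(kind=review.kind)
    new_reference = reference.copy()
    for rule in review:
        if not rule.decided and rx.fullmatch(rule.unit):
            new_reference.add(
                UnitRule(
                    unit=rule.unit,
                    context=rule.context,
                    count=rule.count,
                    action=Action.ALLOW,
                    category=category if review.kind == "word" else None,
                )
            )
        else:
            new_review.add(replace(rule))
    return new_review, new_reference


# ------------------------------------------------------- phrase-type rules

_PATTERN_TOKEN_RE = re.compile(r"\[([^\[\]()]+)\((\d+)\)\]")
_TEMPLATE_REF_RE = re.compile(r"\[(\d+)\]")

PHRASE_COLUMNS = ("name", "pattern", "valid", "standard_form")


@dataclass(frozen=True)
class PhrasePattern:
    """A named category sequence with a validity verdict and output template.

    ``standard_form`` is literal text with ``[i]`` placeholders referring to
    the i-th word of the matched phrase; it may be empty only for invalid
    patterns (which are never rewritten).
    """

    name: str
    categories: tuple[str, ...]
    valid: bool
    standard_form: str = ""

    def __post_init__(self) -> None:
        n = len(self.categories)
        refs = [int(m) for m in _TEMPLATE_REF_RE.findall(self.standard_form)]
        bad = [i for i in refs if i >= n]
        if bad:
            raise MalformedRuleError(
                f"pattern {self.name!r}: standard form references index "
                f"{bad[0]} but the pattern has only {n} slots"
            )
        if self.valid and not self.standard_form:
            raise MalformedRuleError(
                f"pattern {self.name!r} is valid but has no standard form"
            )

    @property
    def cat_string(self) -> str:
        return "".join(f"[{c}({i})]" for i, c in enumerate(self.categories))


def parse_pattern_string(name: str, text: str) -> tuple[str, ...]:
    """Parse a pattern column like ``[number(0)] [unit(1)]`` into categories.

    Whitespace between category tokens carries no meaning and is ignored.
    Indices must run 0..n-1 in order.
    """
    matches = list(_PATTERN_TOKEN_RE.finditer(text))
    stripped = _PATTERN_TOKEN_RE.sub("", text).strip()
    if stripped or not matches:
        raise MalformedRuleError(f"pattern {name!r}: cannot parse pattern string {text!r}")
    categories = []
    for expected, m in enumerate(matches):
        if int(m.group(2)) != expected:
            raise MalformedRuleError(
                f"pattern {name!r}: indices must be 0..n-1 in order, got {text!r}"
            )
        categories.append(m.group(1).strip())
    return tuple(categories)


def generate_blank_phrase_ruleset(path: str | Path) -> None:
    """Write an empty phrase-type ruleset file with headers."""
    Path(path).write_text("\t".join(PHRASE_COLUMNS) + "\n", encoding="utf-8")


def load_phrase_ruleset(path: str | Path) -> list[PhrasePattern]:
    """Load a phrase-type ruleset TSV; create a blank file if absent."""
    path = Path(path)
    if not path.exists():
        generate_blank_phrase_ruleset(path)
        return []
    patterns: list[PhrasePattern] = []
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        return patterns
    header = lines[0].split("\t")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = dict(zip(header, line.split("\t")))
        name = cells.get("name", f"line {lineno}")
        valid = cells.get("valid", "").strip().upper() in ("Y", "YES", "1", "TRUE")
        patterns.append(
            PhrasePattern(
                name=name,
                categories=parse_pattern_string(name, cells.get("pattern", "")),
                valid=valid,
                standard_form=cells.get("standard_form", "").strip(),
            )
        )
    return patterns


def save_phrase_ruleset(patterns: Sequence[PhrasePattern], path: str | Path) -> None:
    lines = ["\t".join(PHRASE_COLUMNS)]
    for p in patterns:
        pattern_text = " ".join(f"[{c}({i})]" for i, c in enumerate(p.categories))
        lines.append(
            "\t".join([p.name, pattern_text, "Y" if p.valid else "N", p.standard_form])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
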