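"""Pattern-based phrase normalization.

Each word of a (character- and word-valid) item is assigned a category —
from the word reference file's ``category`` column, from a small set of
built-in auto-categorizers, or ``unknown`` — producing a categorization
string such as ``[number(0)][unit(1)][statistical(2)]`` for "6 week mean".
That string is matched against the dataset's phrase-type ruleset; items
matching a pattern flagged valid are rewritten into the pattern's standard
form (``[2]: [0] [1]`` -> "mean: 6 week"), items matching an invalid
pattern or no pattern at all fail phrase validation.

Input delimiters are discarded at this stage: the standard-form template
supplies all output separators.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .rule_store import PhrasePattern, RuleSet, _TEMPLATE_REF_RE
from .tokenizer import DEFAULT_DELIMITERS, Token, is_protected, split_words

logger = logging.getLogger(__name__)

#: digits with optional decimal point / internal comma and an optional
#: single trailing letter (sub-panel references like "2a")
NUMBER_RE = re.compile(r"\d+(?:[.,]\d+)*[a-z]?")
#: four alphanumeric characters starting with a digit (PDB-style id)
PDB_ID_RE = re.compile(r"\d[a-z0-9]{3}")


@dataclass
class CategorizedPhrase:
    tokens: list[Token]
    categories: list[str]

    @property
    def cat_string(self) -> str:
        return "".join(f"[{c}({i})]" for i, c in enumerate(self.categories))

    @property
    def texts(self) -> list[str]:
        return [t.text for t in self.tokens]


@dataclass
class PhraseResult:
    input: str
    cat_string: str
    matched_pattern: str | None = None
    valid: bool = False
    output: str | None = None


def categorize(
    item: str,
    word_reference: RuleSet,
    delimiters: Iterable[str] = DEFAULT_DELIMITERS,
    protected_prefixes: Sequence[str] = (),
    enable_pdb_autocategory: bool = False,
) -> CategorizedPhrase:
    """Assign a category to every word of *item*.

    Priority per token: word-reference category column; built-in
    auto-categorizers (numbers; optionally PDB-style ids; opaque protected
    items categorize as ``url``); otherwise ``unknown``.
    """
    tokens = split_words(item, delimiters, protected_prefixes)
    if tokens and is_protected(item, protected_prefixes):
        return CategorizedPhrase(tokens=tokens, categories=["url"])
    reference_categories = word_reference.categories()
    categories = []
    for tok in tokens:
        cat = reference_categories.get(tok.text)
        if cat is None:
            # 4-character ids with a letter are unambiguous; all-digit
            # tokens stay numbers even when they could be ids
            if (enable_pdb_autocategory and PDB_ID_RE.fullmatch(tok.text)
                    and not tok.text.isdigit()):
                cat = "pdb_id"
            elif NUMBER_RE.fullmatch(tok.text):
                cat = "number"
            else:
                cat = "unknown"
        categories.append(cat)
    return CategorizedPhrase(tokens=tokens, categories=categories)


def match(cat: CategorizedPhrase, ruleset: Sequence[PhrasePattern]) -> PhraseResult:
    """Match a categorized phrase against the ruleset (first match wins)."""
    sequence = tuple(cat.categories)
    for pattern in ruleset:
        if pattern.categories == sequence:
            return PhraseResult(
                input="", cat_string=cat.cat_string,
                matched_pattern=pattern.name, valid=pattern.valid,
            )
    return PhraseResult(input="", cat_string=cat.cat_string, matched_pattern=None, valid=False)


def apply_standard_form(cat: CategorizedPhrase, pattern: PhrasePattern) -> str:
    """Rewrite the phrase into the pattern's standard form."""
    if not pattern.valid:
        raise ValueError(f"pattern {pattern.name!r} is not valid; nothing to rewrite")
    texts = cat.texts

    def _sub(m: re.Match) -> str:
        return texts[int(m.group(1))]

    return _TEMPLATE_REF_RE.sub(_sub, pattern.standard_form)


def normalize_phrase(
    item: str,
    word_reference: RuleSet,
    ruleset: Sequence[PhrasePattern],
    delimiters: Iterable[str] = DEFAULT_DELIMITERS,
    protected_prefixes: Sequence[str] = (),
    enable_pdb_autocategory: bool = False,
) -> PhraseResult:
    """Categorize, match and (when valid) rewrite one item."""
    cat = categorize(item, word_reference, delimiters, protected_prefixes,
                     enable_pdb_autocategory)
    result = match(cat, ruleset)
    result.input = item
    if result.valid:
        pattern = next(p for p in ruleset if p.name == result.matched_pattern)
        result.output = apply_standard_form(cat, pattern)
    return result


def lint_ruleset(ruleset: Sequence[PhrasePattern]) -> list[str]:
    """Static checks on a phrase-type ruleset; returns warning messages.

    Flags duplicate category sequences (only the first can ever match),
    pattern slots a valid standard form drops, and valid standard forms
    whose own output would not re-match any pattern in the ruleset (a
    fixed-point/idempotence requirement).  Templates containing literal
    words cannot be statically re-categorized and are flagged as unchecked.
    """
    warnings: list[str] = []
    seen: dict[tuple[str, ...], str] = {}
    sequences = {p.categories for p in ruleset}
    for p in ruleset:
        if p.categories in seen:
            warnings.append(
                f"pattern {p.name!r} duplicates the category sequence of "
                f"{seen[p.categories]!r} and can never match"
            )
        else:
            seen[p.categories] = p.name
        if not p.valid:
            continue
        refs = [int(m) for m in _TEMPLATE_REF_RE.findall(p.standard_form)]
        dropped = sorted(set(range(len(p.categories))) - set(refs))
        if dropped:
            warnings.append(
                f"pattern {p.name!r}: standard form drops token index(es) {dropped}"
            )
        literal = _TEMPLATE_REF_RE.sub("", p.standard_form)
        if any(ch not in DEFAULT_DELIMITERS for ch in literal):
            warnings.append(
                f"pattern {p.name!r}: standard form contains literal words; "
                "idempotence not statically checkable"
            )
        else:
            out_sequence = tuple(p.categories[i] for i in refs)
            if out_sequence not in sequences:
                warnings.append(
                    f"pattern {p.name!r}: its standard-form output "
                    f"({out_sequence}) matches no pattern, so phrase "
                    "normalization would not be idempotent"
                )
    return warnings
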