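"""Shared stage engine: apply character or word rules to one data item.

Both stages follow the same action-decision semantics:

* ``replace_with`` — the unit is substituted with the decision text;
* ``remove`` — the unit is deleted;
* ``invalidate`` — the item fails validation and is passed through unmodified;
* ``allow`` — the unit is an accepted text unit for validation.

An item is stage-valid when, after replacements and removals, every
remaining unit is allowed (character stage: allowed by rule or member of the
always-valid default set; word stage: allowed by rule).  Invalid items are
carried through byte-identical so nothing is lost for later re-curation.

Rule application order within a stage is fixed for determinism: all
replacements, then removals, then the invalidate check, then the allow
check.  Replacement output is not re-scanned within the same run — any new
units it introduces surface in the next review cycle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .metrics import levenshtein
from .rule_store import DEFAULT_VALID_CHARS, RuleSet
from .tokenizer import DEFAULT_DELIMITERS, Token, is_protected, rejoin, split_words


class RuleConsistencyError(ValueError):
    """A replacement rule produces text that another rule invalidates."""


@dataclass
class StageResult:
    """Outcome of one normalization stage for one data item."""

    input: str
    output: str
    valid: bool
    invalidating_units: list[str] = field(default_factory=list)
    distance: int = 0


def _invalid(item: str, units: Iterable[str]) -> StageResult:
    return StageResult(
        input=item, output=item, valid=False,
        invalidating_units=sorted(set(units)), distance=0,
    )


def check_char_rule_consistency(rules: RuleSet) -> None:
    """Reject rule sets whose replacement text contains an invalidated character."""
    invalidated = rules.invalidated()
    for unit, value in rules.replacements().items():
        hit = [ch for ch in value if ch in invalidated]
        if hit:
            raise RuleConsistencyError(
                f"replacement for {unit!r} introduces invalidated character(s) "
                f"{hit!r} (rule conflict between replace_with and invalidate)"
            )


def apply_char_rules(
    item: str,
    rules: RuleSet,
    defaults: frozenset[str] | set[str] = DEFAULT_VALID_CHARS,
    lowercase: bool = True,
) -> StageResult:
    """Apply character rules to *item* and flag character-level validity.

    Letters are lowercased first (uppercase letters sit outside the default
    valid set; case differences are treated as pure character variance), then
    replacements and removals run in a single left-to-right pass.  The
    Levenshtein distance is measured between the original item and the
    stage output.
    """
    check_char_rule_consistency(rules)
    replacements = rules.replacements()
    removed = rules.removed()
    invalidated = rules.invalidated()
    allowed = defaults | rules.allowed()

    work = item.lower() if lowercase else item
    out_chars: list[str] = []
    for ch in work:
        if ch in replacements:
            value = replacements[ch]
            out_chars.append(value.lower() if lowercase else value)
        elif ch in removed:
            continue
        else:
            out_chars.append(ch)
    output = "".join(out_chars)

    bad = [ch for ch in output if ch in invalidated]
    if bad:
        return _invalid(item, bad)
    unallowed = [ch for ch in output if ch not in allowed]
    if unallowed:
        return _invalid(item, unallowed)
    return StageResult(
        input=item, output=output, valid=True,
        invalidating_units=[], distance=levenshtein(item, output),
    )


def _drop_token(tokens: list[Token], index: int) -> list[Token]:
    """Remove tokens[index], collapsing the doubled delimiter run.

    The surviving delimiter is the removed token's left run, except at a
    string boundary where the run vanishes entirely (so "6-10 week old"
    loses both "old" and its leading space).
    """
    tok = tokens[index]
    merged = "" if (tok.left_delim == "" or tok.right_delim == "") else tok.left_delim
    out = []
    for i, t in enumerate(tokens):
        if i == index:
            continue
        if i == index - 1:
            t = Token(t.text, t.start, t.left_delim, merged)
        elif i == index + 1:
            t = Token(t.text, t.start, merged, t.right_delim)
        out.append(t)
    return out


def apply_word_rules(
    item: str,
    rules: RuleSet,
    delimiters: Iterable[str] = DEFAULT_DELIMITERS,
    protected_prefixes: Sequence[str] = (),
    auto_allow: Sequence[str] = (),
) -> StageResult:
    """Apply word rules to a character-normalized item.

    Tokens are matched whole and case-sensitively (everything is lowercase
    after the character stage).  Replacements keep the surrounding
    delimiters; removals collapse the doubled delimiter.  The item is valid
    when every untouched token carries an allow rule; replaced tokens count
    as decided and are not re-checked within the run.

    ``auto_allow`` holds regular expressions whose full matches count as
    allowed without an explicit rule row — the validation-time face of the
    bulk mass-allow used for open-ended unit families such as plain numbers
    or PDB-style identifiers.

    Items with a protected prefix (URLs) are opaque: passed through
    unchanged and valid.
    """
    if is_protected(item, protected_prefixes):
        return StageResult(input=item, output=item, valid=True, distance=0)

    tokens = split_words(item, delimiters, protected_prefixes)
    replacements = rules.replacements()
    removed = rules.removed()
    invalidated = rules.invalidated()
    allowed = rules.allowed()

    bad = [t.text for t in tokens if t.text in invalidated]
    if bad:
        return _invalid(item, bad)

    replaced_positions: set[int] = set()
    out_tokens: list[Token] = []
    for t in tokens:
        if t.text in replacements:
            replaced_positions.add(len(out_tokens))
            t = Token(replacements[t.text], t.start, t.left_delim, t.right_delim)
        out_tokens.append(t)

    i = 0
    while i < len(out_tokens):
        if i not in replaced_positions and out_tokens[i].text in removed:
            out_tokens = _drop_token(out_tokens, i)
            replaced_positions = {p - 1 if p > i else p for p in replaced_positions}
        else:
            i += 1

    auto = [re.compile(p) for p in auto_allow]
    pending = [
        t.text
        for i, t in enumerate(out_tokens)
        if i not in replaced_positions
        and t.text not in allowed
        and not any(rx.fullmatch(t.text) for rx in auto)
    ]
    if pending:
        return _invalid(item, pending)

    output = rejoin(out_tokens) if out_tokens else ("" if tokens else item)
    return StageResult(
        input=item, output=output, valid=True,
        invalidating_units=[], distance=levenshtein(item, output),
    )
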