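"""Bundled demonstration rulesets for the age and data-location demos.

These reproduce the published sample rules for both fields — the
character decisions (allow "=", en dash -> hyphen, "&" -> "and",
invalidate "€"), the word decisions (drop "old", "wk" -> "week",
"fig" -> "figure", allow "additional file" parts, unit/statistical/range
categories) and the phrase-type patterns (ranges, statistical phrases,
unitless numbers invalid, PDB ids, location+number, URLs) — plus the small
amount of extra vocabulary the synthetic corpora exercise (spelled-out
numbers, plural and abbreviated units, figure/table/page head words).

Regexes for open-ended unit families (numbers, S-numbers, PDB-style ids)
are exposed as mass-allow patterns rather than materialized rows.
"""

from __future__ import annotations

from .rule_store import Action, PhrasePattern, RuleSet, UnitRule

#: URL prefixes treated as opaque in the data-location demo.
DATALOC_PROTECTED_PREFIXES = ("https://", "http://")

#: mass-allow (regex, category) pairs per dataset
AGE_MASS_ALLOW: tuple[tuple[str, str | None], ...] = (
    (r"\d+(?:[.,]\d+)*", "number"),
)
DATALOC_MASS_ALLOW: tuple[tuple[str, str | None], ...] = (
    (r"\d+(?:[.,]\d+)*[a-z]?", "number"),
    (r"s\d+", None),
    (r"\d[a-z0-9]{3}", "pdb_id"),
    (r"[a-z]", None),  # bare sub-panel letters from "2A,B,C"-style lists
)

_SPELLED_NUMBERS = {
    "one": "1", "two": "2", "three": "3", "four": "4", "five": "5",
    "six": "6", "seven": "7", "eight": "8", "nine": "9", "ten": "10",
    "eleven": "11", "twelve": "12", "thirteen": "13", "fourteen": "14",
    "fifteen": "15", "sixteen": "16", "seventeen": "17", "eighteen": "18",
    "nineteen": "19", "twenty": "20",
}

_UNIT_ABBREVIATIONS = {
    "wk": "week", "wks": "week", "yr": "year", "yrs": "year",
    "mo": "month", "mos": "month", "hr": "hour", "hrs": "hour",
}

_UNITS = ("week", "month", "year", "day", "hour")


def _rule(unit: str, action: Action, value: str | None = None,
          category: str | None = None) -> UnitRule:
    return UnitRule(unit=unit, action=action, value=value, category=category)


def age_char_reference() -> RuleSet:
    rules = RuleSet(kind="char")
    rules.add(_rule("=", Action.ALLOW))
    rules.add(_rule("–", Action.REPLACE_WITH, value="-"))  # en dash
    rules.add(_rule("€", Action.INVALIDATE))  # euro sign
    return rules


def dataloc_char_reference() -> RuleSet:
    rules = RuleSet(kind="char")
    rules.add(_rule("&", Action.REPLACE_WITH, value="and"))
    rules.add(_rule("–", Action.REPLACE_WITH, value="-"))
    rules.add(_rule("€", Action.INVALIDATE))
    rules.add(_rule("=", Action.ALLOW))
    return rules


def age_word_reference() -> RuleSet:
    rules = RuleSet(kind="word")
    for word, digits in _SPELLED_NUMBERS.items():
        rules.add(_rule(word, Action.REPLACE_WITH, value=digits))
    for abbr, full in _UNIT_ABBREVIATIONS.items():
        rules.add(_rule(abbr, Action.REPLACE_WITH, value=full))
    for unit in _UNITS:
        rules.add(_rule(unit + "s", Action.REPLACE_WITH, value=unit))
        rules.add(_rule(unit, Action.ALLOW, category="unit"))
    for word in ("old", "age", "aged"):
        rules.add(_rule(word, Action.REMOVE))
    for word in ("mean", "median", "average"):
        rules.add(_rule(word, Action.ALLOW, category="statistical"))
    rules.add(_rule("to", Action.ALLOW, category="range_indicator"))
    for word in ("adult", "juvenile", "newborn"):
        rules.add(_rule(word, Action.ALLOW, category="life_stage"))
    rules.add(_rule("adults", Action.REPLACE_WITH, value="adult"))
    rules.add(_rule("juveniles", Action.REPLACE_WITH, value="juvenile"))
    rules.add(_rule("newborns", Action.REPLACE_WITH, value="newborn"))
    return rules


def dataloc_word_reference() -> RuleSet:
    rules = RuleSet(kind="word")
    for variant in ("fig", "figs", "figures"):
        rules.add(_rule(variant, Action.REPLACE_WITH, value="figure"))
    rules.add(_rule("tables", Action.REPLACE_WITH, value="table"))
    for variant in ("suppl", "supplementary"):
        rules.add(_rule(variant, Action.REPLACE_WITH, value="supplemental"))
    for variant in ("pg", "p", "pages"):
        rules.add(_rule(variant, Action.REPLACE_WITH, value="page"))
    for word in ("figure", "table", "page", "data", "set", "file",
                 "information", "supplemental", "additional", "abstract"):
        rules.add(_rule(word, Action.ALLOW, category="location"))
    rules.add(_rule("pdb", Action.ALLOW, category="pdb"))
    for word in ("and", "supporting", "or"):
        rules.add(_rule(word, Action.ALLOW))
    return rules


def age_phrase_ruleset() -> list[PhrasePattern]:
    return [
        PhrasePattern("number unit", ("number", "unit"), True, "[0] [1]"),
        PhrasePattern("range", ("number", "range_indicator", "number", "unit"),
                      True, "[0]-[2] [3]"),
        PhrasePattern("compact range", ("number", "number", "unit"),
                      True, "[0]-[1] [2]"),
        PhrasePattern("statistical", ("statistical", "number", "unit"),
                      True, "[0]: [1] [2]"),
        PhrasePattern("trailing statistical", ("number", "unit", "statistical"),
                      True, "[2]: [0] [1]"),
        PhrasePattern("life stage", ("life_stage",), True, "[0]"),
        PhrasePattern("unitless range", ("number", "range_indicator", "number"),
                      False),
        PhrasePattern("compact unitless range", ("number", "number"), False),
        PhrasePattern("number", ("number",), False),
    ]


def dataloc_phrase_ruleset() -> list[PhrasePattern]:
    return [
        PhrasePattern("loc number", ("location", "number"), True, "[0] [1]"),
        PhrasePattern("qualified loc number", ("location", "location", "number"),
                      True, "[0] [1] [2]"),
        PhrasePattern("pdb id", ("pdb", "pdb_id"), True, "[0] [1]"),
        PhrasePattern("all-digit pdb id", ("pdb", "number"), True, "[0] [1]"),
        PhrasePattern("url", ("url",), True, "[0]"),
        PhrasePattern("location", ("location",), True, "[0]"),
        PhrasePattern("number", ("number",), False),
        PhrasePattern("bare pdb id", ("pdb_id",), False),
    ]


def demo_rulesets(dataset: str) -> dict:
    """All demonstration rule objects for ``"age"`` or ``"data_loc"``."""
    if dataset == "age":
        return {
            "char_reference": age_char_reference(),
            "word_reference": age_word_reference(),
            "phrase_ruleset": age_phrase_ruleset(),
            "mass_allow": AGE_MASS_ALLOW,
            "protected_prefixes": (),
            "enable_splitter": False,
            "enable_pdb_autocategory": False,
        }
    if dataset == "data_loc":
        return {
            "char_reference": dataloc_char_reference(),
            "word_reference": dataloc_word_reference(),
            "phrase_ruleset": dataloc_phrase_ruleset(),
            "mass_allow": DATALOC_MASS_ALLOW,
            "protected_prefixes": DATALOC_PROTECTED_PREFIXES,
            "enable_splitter": True,
            "enable_pdb_autocategory": True,
        }
    raise ValueError(f"unknown demo dataset {dataset!r} (use 'age' or 'data_loc')")
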