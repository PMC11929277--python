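"""Synthetic messy corpora with known ground truth.

Two generators emulate the structure of the curated free-text fields the
engine was designed around:

* **age-style** strings — numbers with time units, ranges, statistical
  qualifiers (mean/median/average), life-stage words — with controllable
  variance: en dashes for hyphens, abbreviated ("wk") and plural ("weeks")
  units, spelled-out numbers ("Six"), "N to M" range phrasing, leading
  capitals and "old"/"age" filler words.  Unitless numbers and ranges are
  generated as intentionally ambiguous items whose ground truth is the
  INVALID verdict.

* **data-location-style** strings — figure/table/page references with
  list-like enumerations and letter suffixes ("Fig. 2A,B"), PDB-style
  4-character identifiers, fixed-prefix URLs whose path is 9 uppercase
  letters, and bare numbers (INVALID).

Ground truth stores the full verdict — the canonical string (age) or the
canonical segment list (data-location), or INVALID — so pipeline outputs
can be scored by exact match.  Identical spec + seed reproduce the corpus
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: ground-truth sentinel for items whose correct outcome is invalidation
INVALID = "INVALID"

URL_PREFIX = "https://hla-ligand-atlas.org/peptide/"

_DEFAULT_NOISE = {
    "char_substitution": 0.15,   # hyphen -> en dash
    "unit_abbreviation": 0.15,   # week -> wk
    "plural_unit": 0.35,         # week -> weeks
    "spelled_number": 0.10,      # 6 -> six
    "dash_variant": 0.15,        # 6-8 -> 6 to 8
    "case_upper": 0.25,          # leading capital / uppercase ids
    "age_qualifier": 0.20,       # trailing "old" / "age" filler
    "phrase_shuffle": 0.50,      # alternative phrase arrangement
    "list_length_mean": 3.0,     # mean enumeration length (data-location)
    "head_elision": 0.60,        # "figure 1, figure 2" -> "figure 1, 2"
    "letter_suffix": 0.20,       # "figure 2" -> "figure 2a,b"
    "url_fraction": 0.30,
    "pdb_fraction": 0.15,
}

_NUMBER_WORDS = {
    1: "one", 2: "two", 3: "three", 4: "four", 5: "five", 6: "six",
    7: "seven", 8: "eight", 9: "nine", 10: "ten", 11: "eleven",
    12: "twelve", 13: "thirteen", 14: "fourteen", 15: "fifteen",
    16: "sixteen", 17: "seventeen", 18: "eighteen", 19: "nineteen",
    20: "twenty",
}

_ABBREV = {"week": "wk", "year": "yr", "month": "mo", "hour": "hr"}

_UNITS = ("week", "year", "month", "day", "hour")
_UNIT_WEIGHTS = (0.35, 0.30, 0.20, 0.10, 0.05)

_LIFE_STAGES = ("adult", "juvenile", "newborn")

_HEADS = (  # canonical head, messy variants
    ("figure", ("fig.", "figs.", "figure", "figures")),
    ("table", ("table", "tables")),
    ("page", ("p.", "pg.", "page")),
    ("supplemental figure", ("suppl fig.", "supplementary fig.", "supplementary figs.")),
)


@dataclass
class FixtureSpec:
    """Size, seed and per-variance-class noise rates for a synthetic corpus."""

    n_items: int = 100
    seed: int = 0
    noise_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        unknown = set(self.noise_rates) - set(_DEFAULT_NOISE)
        if unknown:
            raise ValueError(f"unknown noise classes: {sorted(unknown)}")
        merged = dict(_DEFAULT_NOISE)
        merged.update(self.noise_rates)
        for key, value in merged.items():
            if key != "list_length_mean" and not 0.0 <= value <= 1.0:
                raise ValueError(f"noise rate {key} must be in [0, 1], got {value}")
        self.noise_rates = merged

    def zero_noise(self) -> "FixtureSpec":
        """Copy of this spec with every noise probability set to zero."""
        rates = {k: 0.0 for k in _DEFAULT_NOISE if k != "list_length_mean"}
        rates["list_length_mean"] = self.noise_rates["list_length_mean"]
        return FixtureSpec(n_items=self.n_items, seed=self.seed, noise_rates=rates)


def _hit(rng: np.random.Generator, rate: float) -> bool:
    return rate > 0 and rng.random() < rate


def _unit_surface(rng: np.random.Generator, unit: str, noise: dict[str, float]) -> str:
    surface = unit
    if _hit(rng, noise["unit_abbreviation"]) and unit in _ABBREV:
        surface = _ABBREV[unit]
    if _hit(rng, noise["plural_unit"]):
        surface += "s"
    return surface


def _number_surface(rng: np.random.Generator, n: str, noise: dict[str, float]) -> str:
    if _hit(rng, noise["spelled_number"]) and n.isdigit() and int(n) in _NUMBER_WORDS:
        return _NUMBER_WORDS[int(n)]
    return n


def _dash_surface(rng: np.random.Generator, noise: dict[str, float]) -> str:
    if _hit(rng, noise["dash_variant"]):
        return " to "
    if _hit(rng, noise["char_substitution"]):
        return "–"  # en dash
    return "-"


def _casing(rng: np.random.Generator, text: str, noise: dict[str, float]) -> str:
    if _hit(rng, noise["case_upper"]):
        return text[:1].upper() + text[1:]
    return text


def generate_age_corpus(spec: FixtureSpec) -> list[tuple[str, str]]:
    """Generate ``n_items`` (messy, canonical-or-INVALID) age-style pairs."""
    rng = np.random.default_rng(spec.seed)
    noise = spec.noise_rates
    out: list[tuple[str, str]] = []
    forms = ("simple", "range", "statistical", "life_stage", "bare_number", "bare_range")
    weights = (0.35, 0.25, 0.20, 0.05, 0.10, 0.05)
    for _ in range(spec.n_items):
        form = rng.choice(forms, p=weights)
        unit = rng.choice(_UNITS, p=_UNIT_WEIGHTS)
        if form == "simple":
            n = str(rng.integers(1, 90))
            canonical = f"{n} {unit}"
            messy = f"{_number_surface(rng, n, noise)} {_unit_surface(rng, unit, noise)}"
            if _hit(rng, noise["age_qualifier"]):
                messy += " old"
        elif form == "range":
            a = int(rng.integers(1, 80))
            b = int(a + rng.integers(1, 12))
            canonical = f"{a}-{b} {unit}"
            messy = (
                f"{_number_surface(rng, str(a), noise)}{_dash_surface(rng, noise)}"
                f"{_number_surface(rng, str(b), noise)} {_unit_surface(rng, unit, noise)}"
            )
            if _hit(rng, noise["age_qualifier"]):
                messy += " old"
        elif form == "statistical":
            stat = rng.choice(("mean", "median", "average"))
            n = str(round(rng.uniform(0.5, 90.0), 1)) if _hit(rng, 0.5) else str(rng.integers(1, 90))
            canonical = f"{stat}: {n} {unit}"
            num, un = _number_surface(rng, n, noise), _unit_surface(rng, unit, noise)
            if _hit(rng, noise["phrase_shuffle"]):
                arrangement = rng.choice(
                    (f"{stat} {num} {un}", f"{stat} age = {num} {un}", f"{num} {un} {stat}")
                )
                messy = str(arrangement)
            else:
                messy = f"{stat}: {num} {un}"
        elif form == "life_stage":
            stage = str(rng.choice(_LIFE_STAGES))
            canonical = stage
            messy = stage + ("s" if _hit(rng, noise["plural_unit"]) else "")
        elif form == "bare_number":
            n = str(rng.integers(1, 90))
            canonical = INVALID
            messy = _number_surface(rng, n, noise)
        else:  # bare_range
            a = int(rng.integers(1, 80))
            b = int(a + rng.integers(1, 12))
            canonical = INVALID
            messy = (
                f"{_number_surface(rng, str(a), noise)}{_dash_surface(rng, noise)}"
                f"{_number_surface(rng, str(b), noise)}"
            )
        out.append((_casing(rng, messy, noise), canonical))
    return out


def _random_pdb_id(rng: np.random.Generator) -> str:
    alphanum = "abcdefghijklmnopqrstuvwxyz0123456789"
    return str(rng.integers(1, 10)) + "".join(rng.choice(list(alphanum), size=3))


def generate_dataloc_corpus(spec: FixtureSpec) -> list[tuple[str, list[str] | str]]:
    """Generate (messy, canonical_segments-or-INVALID) data-location pairs."""
    rng = np.random.default_rng(spec.seed)
    noise = spec.noise_rates
    url_fraction = noise["url_fraction"]
    pdb_fraction = noise["pdb_fraction"]
    bare_fraction = max(0.0, min(0.05, 1.0 - url_fraction - pdb_fraction))
    list_fraction = max(0.0, 1.0 - url_fraction - pdb_fraction - bare_fraction)
    kinds = ("url", "pdb", "bare_number", "list")
    weights = np.array([url_fraction, pdb_fraction, bare_fraction, list_fraction])
    weights = weights / weights.sum()

    out: list[tuple[str, list[str] | str]] = []
    for _ in range(spec.n_items):
        kind = rng.choice(kinds, p=weights)
        if kind == "url":
            path = "".join(rng.choice(list("abcdefghijklmnopqrstuvwxyz"), size=9))
            messy = URL_PREFIX + (path.upper() if _hit(rng, noise["case_upper"]) else path)
            out.append((messy, [URL_PREFIX + path]))
        elif kind == "pdb":
            k = 1 + int(rng.poisson(max(0.0, noise["list_length_mean"] - 1)))
            ids = [_random_pdb_id(rng) for _ in range(k)]
            upper = _hit(rng, noise["case_upper"])
            shown = [i.upper() if upper else i for i in ids]
            pdb_word = "PDB" if upper else "pdb"
            sep = ": " if _hit(rng, noise["phrase_shuffle"]) else " "
            if _hit(rng, noise["head_elision"]):
                messy = f"{pdb_word}{sep}" + ", ".join(shown)
            else:
                messy = ", ".join(f"{pdb_word}{sep}{i}" for i in shown)
            out.append((messy, [f"pdb {i}" for i in ids]))
        elif kind == "bare_number":
            out.append((str(rng.integers(1, 200)), INVALID))
        else:  # reference list
            canonical_head, variants = _HEADS[rng.integers(0, len(_HEADS))]
            if _hit(rng, noise["unit_abbreviation"]) or _hit(rng, noise["plural_unit"]):
                head = str(rng.choice(variants))
            else:
                head = canonical_head
            head = _casing(rng, head, noise)
            if _hit(rng, noise["letter_suffix"]):
                n = int(rng.integers(1, 20))
                letters = "abc"[: 1 + int(rng.integers(1, 3))]
                shown_letters = letters.upper() if _hit(rng, noise["case_upper"]) else letters
                messy = f"{head} {n}" + shown_letters[0] + "".join(
                    f",{c}" for c in shown_letters[1:]
                )
                canonical = [f"{canonical_head} {n}{c}" for c in letters]
            else:
                k = min(12, 1 + int(rng.poisson(max(0.0, noise["list_length_mean"] - 1))))
                numbers = sorted(rng.choice(np.arange(1, 30), size=k, replace=False))
                if _hit(rng, noise["head_elision"]):
                    parts = [f"{head} {numbers[0]}"] + [str(n) for n in numbers[1:]]
                else:
                    parts = [f"{head} {n}" for n in numbers]
                if len(parts) > 1 and _hit(rng, noise["phrase_shuffle"]):
                    messy = ", ".join(parts[:-1]) + " and " + parts[-1]
                else:
                    messy = ", ".join(parts)
                canonical = [f"{canonical_head} {n}" for n in numbers]
            out.append((messy, canonical))
    return out


def write_corpus_tsv(
    corpus: Sequence[tuple[str, str | list[str]]], path: str | Path
) -> None:
    """Write a (messy, ground_truth) corpus as two-column TSV.

    Segment-list ground truths are serialized with a ``|`` separator.
    """
    lines = ["messy\tground_truth"]
    for messy, truth in corpus:
        serialized = "|".join(truth) if isinstance(truth, list) else truth
        lines.append(f"{messy}\t{serialized}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_items_tsv(items: Sequence[str], path: str | Path) -> None:
    """Write just the messy column as a one-column data-item TSV."""
    Path(path).write_text("item\n" + "\n".join(items) + "\n", encoding="utf-8")
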