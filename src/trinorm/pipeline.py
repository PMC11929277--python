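"""Stage orchestration: config, file layout, review cycle, logging.

Each stage reads the previous stage's output file from the working
directory, migrates decided review rows into the reference rule bank,
applies the rules, writes its own output plus a refreshed review file, and
logs the counts (items, valid, invalid, new review rows).  All files are
UTF-8 TSV keyed by the dataset name::

    <name>_char_review.tsv    <name>_char_reference.tsv  <name>_char_output.tsv
    <name>_word_review.tsv    <name>_word_reference.tsv  <name>_word_output.tsv
    <name>_split_output.tsv   <name>_phrase_types.tsv    <name>_phrase_output.tsv
    <name>_metrics.tsv

Two consecutive runs with unchanged rule files produce byte-identical
outputs.  Items that fail a stage are carried through every later output
with their validity flag — never dropped.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from . import list_splitter, rule_store
from .metrics import ItemMetrics, format_summary, summarize
from .phrase_normalizer import normalize_phrase
from .rule_store import (
    DEFAULT_VALID_CHARS,
    MalformedRuleError,
    RuleSet,
    build_review,
    collect_units,
    load_phrase_ruleset,
    migrate_decided,
)
from .tokenizer import DEFAULT_DELIMITERS, is_protected
from .unit_normalizer import apply_char_rules, apply_word_rules

logger = logging.getLogger(__name__)

STAGES = ("char", "word", "split", "phrase", "metrics")


class PipelineError(RuntimeError):
    """A stage prerequisite is missing or a rule file is malformed."""


@dataclass
class PipelineConfig:
    """Per-dataset pipeline settings (serialized as YAML)."""

    dataset_name: str
    input_path: str
    workdir: str
    delimiter_set: str = "".join(sorted(DEFAULT_DELIMITERS))
    default_valid_chars: str = "".join(sorted(DEFAULT_VALID_CHARS))
    protected_prefixes: list[str] = field(default_factory=list)
    enable_splitter: bool = False
    enable_pdb_autocategory: bool = False
    lowercase: bool = True
    mass_allow: list[list[str | None]] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False), encoding="utf-8"
        )

    # ------------------------------------------------------------- paths

    def file(self, suffix: str) -> Path:
        return Path(self.workdir) / f"{self.dataset_name}_{suffix}.tsv"

    @property
    def delimiters(self) -> frozenset[str]:
        return frozenset(self.delimiter_set)

    @property
    def defaults(self) -> frozenset[str]:
        return frozenset(self.default_valid_chars)

    @property
    def auto_allow(self) -> list[str]:
        return [rx for rx, _ in self.mass_allow]


def read_items(path: str | Path) -> list[str]:
    """Read a one-column data-item TSV (optional ``item`` header line)."""
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"input file not found: {path}")
    lines = path.read_text(encoding="utf-8").splitlines()
    if lines and lines[0].strip() == "item":
        lines = lines[1:]
    return [line for line in lines if line.strip()]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    import csv

    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)


def _read_tsv(path: Path, stage: str) -> pd.DataFrame:
    if not path.exists():
        raise PipelineError(
            f"missing prior-stage output {path}; run the {stage} stage first"
        )
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _log_counts(config: PipelineConfig, stage: str, **counts: int) -> dict:
    payload = {"stage": stage, "dataset": config.dataset_name, **counts,
               "seed": config.seed}
    logger.info(" ".join(f"{k}={v}" for k, v in payload.items()))
    return payload


# ------------------------------------------------------------------ char


def run_char(config: PipelineConfig) -> dict:
    items = read_items(config.input_path)
    work = [i.lower() for i in items] if config.lowercase else items
    review = RuleSet.from_tsv(config.file("char_review"), "char")
    reference = RuleSet.from_tsv(config.file("char_reference"), "char")
    review, reference = migrate_decided(review, reference)
    before = len(review)
    units = collect_units(work, "char")
    review = build_review(units, review, reference, config.defaults)

    results = [
        apply_char_rules(item, reference, config.defaults, config.lowercase)
        for item in items
    ]
    df = pd.DataFrame(
        {
            "original": [r.input for r in results],
            "normalized": [r.output for r in results],
            "valid": [int(r.valid) for r in results],
            "invalidating_units": ["|".join(r.invalidating_units) for r in results],
            "distance": [r.distance for r in results],
        }
    )
    _write_tsv(df, config.file("char_output"))
    review.to_tsv(config.file("char_review"))
    reference.to_tsv(config.file("char_reference"))
    return _log_counts(
        config, "char", items=len(items),
        valid=int(df["valid"].astype(int).sum()),
        invalid=int((1 - df["valid"].astype(int)).sum()),
        new_review_rows=len(review) - before,
    )


# ------------------------------------------------------------------ word


def _check_word_rule_chars(
    word_reference: RuleSet, char_reference: RuleSet, defaults: frozenset[str]
) -> None:
    """Reject word replacements whose text could not pass the char stage."""
    char_ok = defaults | char_reference.allowed()
    invalidated = char_reference.invalidated()
    for unit, value in word_reference.replacements().items():
        bad = [ch for ch in value if ch in invalidated or ch not in char_ok]
        if bad:
            raise MalformedRuleError(
                f"word rule {unit!r} -> {value!r} introduces character(s) {bad!r} "
                "that are invalid at the character stage"
            )


def run_word(config: PipelineConfig) -> dict:
    char_df = _read_tsv(config.file("char_output"), "char")
    review = RuleSet.from_tsv(config.file("word_review"), "word")
    reference = RuleSet.from_tsv(config.file("word_reference"), "word")
    review, reference = migrate_decided(review, reference)
    char_reference = RuleSet.from_tsv(config.file("char_reference"), "char")
    _check_word_rule_chars(reference, char_reference, config.defaults)
    before = len(review)

    entering_mask = char_df["valid"].astype(int) == 1
    entering = char_df.loc[entering_mask, "normalized"].tolist()
    units = collect_units(
        entering, "word", config.delimiters, config.protected_prefixes
    )
    review = build_review(units, review, reference)
    for pattern, category in config.mass_allow:
        review, reference = rule_store.mass_allow(review, reference, pattern, category)

    rows = []
    n_valid = 0
    for _, row in char_df.iterrows():
        entered = int(row["valid"]) == 1
        if entered:
            res = apply_word_rules(
                row["normalized"], reference, config.delimiters,
                config.protected_prefixes, config.auto_allow,
            )
            n_valid += int(res.valid)
            rows.append(
                (row["original"], row["normalized"], res.output, 1,
                 int(res.valid), "|".join(res.invalidating_units), res.distance)
            )
        else:
            rows.append(
                (row["original"], row["normalized"], row["normalized"], 0, 0, "", 0)
            )
    df = pd.DataFrame(
        rows,
        columns=["original", "char_normalized", "word_normalized", "entered",
                 "valid", "invalidating_units", "distance"],
    )
    _write_tsv(df, config.file("word_output"))
    review.to_tsv(config.file("word_review"))
    reference.to_tsv(config.file("word_reference"))
    return _log_counts(
        config, "word", items=len(df), entered=int(entering_mask.sum()),
        valid=n_valid, invalid=int(entering_mask.sum()) - n_valid,
        new_review_rows=len(review) - before,
    )


# ----------------------------------------------------------------- split


def run_split(config: PipelineConfig) -> dict:
    word_df = _read_tsv(config.file("word_output"), "word")
    rows = []
    n_segments = 0
    for original_index, row in word_df.iterrows():
        entered = int(row["entered"]) == 1 and int(row["valid"]) == 1
        if entered:
            segments = list_splitter.split(
                row["word_normalized"], config.protected_prefixes
            )
        else:
            segments = [row["word_normalized"]]
        n_segments += len(segments) if entered else 0
        for split_index, text in enumerate(segments):
            rows.append((original_index, split_index, text, int(entered)))
    df = pd.DataFrame(
        rows, columns=["original_index", "split_index", "segment", "entered"]
    )
    _write_tsv(df, config.file("split_output"))
    return _log_counts(
        config, "split", items=len(word_df), segments=len(df),
        split_segments=n_segments,
    )


# ---------------------------------------------------------------- phrase


def run_phrase(config: PipelineConfig) -> dict:
    word_df = _read_tsv(config.file("word_output"), "word")
    char_df = _read_tsv(config.file("char_output"), "char")
    word_reference = RuleSet.from_tsv(config.file("word_reference"), "word")
    ruleset = load_phrase_ruleset(config.file("phrase_types"))
    if not ruleset:
        logger.warning(
            "phrase-type ruleset %s is empty; every item will fail phrase "
            "validation until patterns are added", config.file("phrase_types"),
        )

    if config.enable_splitter:
        split_df = _read_tsv(config.file("split_output"), "split")
        groups = [
            (int(idx), [(int(r["split_index"]), r["segment"], int(r["entered"]) == 1)
                        for _, r in group.iterrows()])
            for idx, group in split_df.groupby("original_index", sort=True)
        ]
    else:
        groups = [
            (int(idx), [(0, row["word_normalized"], int(row["entered"]) == 1
                         and int(row["valid"]) == 1)])
            for idx, row in word_df.iterrows()
        ]

    rows = []
    metrics: dict[int, ItemMetrics] = {}
    n_entered = n_valid_items = 0
    for original_index, segments in groups:
        word_row = word_df.iloc[original_index]
        original = word_row["original"]
        entered = all(flag for _, _, flag in segments)
        results = []
        for split_index, text, seg_entered in sorted(segments):
            if seg_entered:
                res = normalize_phrase(
                    text, word_reference, ruleset, config.delimiters,
                    config.protected_prefixes, config.enable_pdb_autocategory,
                )
            else:
                res = None
            results.append((split_index, text, res))
        split_count = len(results)
        valid_count = sum(1 for _, _, r in results if r is not None and r.valid)
        metrics[original_index] = ItemMetrics(
            char_distance=int(char_df.iloc[original_index]["distance"]),
            word_distance=int(word_row["distance"]),
            split_phrase_count=split_count,
            phrase_validity_rate=valid_count / split_count,
            protected=is_protected(original.lower(), config.protected_prefixes),
        )
        if entered:
            n_entered += 1
            n_valid_items += int(valid_count == split_count)
        for split_index, text, res in results:
            m = metrics[original_index] if split_index == 0 else None
            rows.append(
                {
                    "original_index": original_index,
                    "split_index": split_index,
                    "original": original,
                    "word_normalized": text,
                    "cat_string": res.cat_string if res else "",
                    "matched_pattern": (res.matched_pattern or "") if res else "",
                    "valid": int(res.valid) if res else 0,
                    "phrase_normalized": (res.output or "") if res else "",
                    "split_phrase_count": m.split_phrase_count if m else "",
                    "phrase_validity_rate": m.phrase_validity_rate if m else "",
                    "char_distance": m.char_distance if m else "",
                    "word_distance": m.word_distance if m else "",
                    "protected": int(m.protected) if m else "",
                }
            )
    df = pd.DataFrame(rows)
    _write_tsv(df, config.file("phrase_output"))
    return _log_counts(
        config, "phrase", items=len(groups), entered=n_entered,
        valid=n_valid_items, invalid=n_entered - n_valid_items,
        segments=len(rows),
    )


# --------------------------------------------------------------- metrics


def run_metrics(config: PipelineConfig) -> dict:
    df = _read_tsv(config.file("phrase_output"), "phrase")
    first = df[df["split_index"].astype(int) == 0]
    items = [
        ItemMetrics(
            char_distance=int(row["char_distance"]),
            word_distance=int(row["word_distance"]),
            split_phrase_count=int(row["split_phrase_count"]),
            phrase_validity_rate=float(row["phrase_validity_rate"]),
            protected=bool(int(row["protected"])),
        )
        for _, row in first.iterrows()
    ]
    summary = summarize(items)
    tables = [summary.assign(scope="all")]
    if any(m.protected for m in items) and not all(m.protected for m in items):
        tables.append(summarize(items, exclude_protected=True).assign(scope="no_url"))
    out = pd.concat(tables).rename_axis("metric").reset_index()
    _write_tsv(out, config.file("metrics"))
    logger.info(format_summary(summary))
    return _log_counts(config, "metrics", items=len(items))


_RUNNERS = {
    "char": run_char,
    "word": run_word,
    "split": run_split,
    "phrase": run_phrase,
    "metrics": run_metrics,
}


def run_stage(stage: str, config: PipelineConfig) -> dict:
    """Run one pipeline stage; returns the logged count summary."""
    if stage not in _RUNNERS:
        raise PipelineError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return _RUNNERS[stage](config)


def run_all(config: PipelineConfig) -> list[dict]:
    """Run char -> word -> (split) -> phrase -> metrics in order."""
    stages = ["char", "word"]
    if config.enable_splitter:
        stages.append("split")
    stages += ["phrase", "metrics"]
    return [run_stage(stage, config) for stage in stages]
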