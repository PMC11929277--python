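import pytest

from trinorm.rule_store import (
    Action,
    MalformedRuleError,
    PhrasePattern,
    RuleSet,
    UnitRule,
    build_review,
    collect_units,
    load_phrase_ruleset,
    mass_allow,
    migrate_decided,
    parse_pattern_string,
    save_phrase_ruleset,
)


class TestBuildReview:
    def test_char_stage_skips_default_valid_characters(self):
        units = collect_units(["mean age = 30 years"], "char")
        review = build_review(
            units, RuleSet(kind="char"), RuleSet(kind="char"),
            default_valid=frozenset("abcdefghijklmnopqrstuvwxyz0123456789 .,-:;()/"),
        )
        assert "=" in review
        for default in ("m", "3", " "):
            assert default not in review

    def test_word_stage_has_no_default_exemptions(self):
        units = collect_units(["8-10 wk"], "word")
        review = build_review(units, RuleSet(kind="word"), RuleSet(kind="word"))
        assert sorted(review.units()) == ["10", "8", "wk"]

    def test_already_decided_unit_gets_no_new_row(self):
        reference = RuleSet([UnitRule("=", action=Action.ALLOW)], kind="char")
        units = collect_units(["age = 30"], "char")
        review = build_review(units, RuleSet(kind="char"), reference,
                              default_valid=frozenset("age 30"))
        assert "=" not in review

    def test_context_sample_is_capped(self):
        items = [f"€ item number {i} with plenty of context padding" for i in range(40)]
        units = collect_units(items, "char")
        (context,) = [c for u, c, _ in units if u == "€"]
        assert len(context) <= 300

    def test_counts_are_occurrence_totals(self):
        units = dict((u, n) for u, _, n in collect_units(["= = =", "="], "char"))
        assert units["="] == 4


class TestMigrateDecided:
    def test_decided_rows_move_to_reference(self):
        review = RuleSet(
            [UnitRule("wk", action=Action.REPLACE_WITH, value="week"),
             UnitRule("glarbl")],
            kind="word",
        )
        new_review, reference = migrate_decided(review, RuleSet(kind="word"))
        assert "wk" in reference and "wk" not in new_review
        assert "glarbl" in new_review and not new_review.get("glarbl").decided

    def test_migration_is_idempotent(self):
        review = RuleSet([UnitRule("old", action=Action.REMOVE), UnitRule("x")],
                         kind="word")
        once = migrate_decided(review, RuleSet(kind="word"))
        twice = migrate_decided(*once)
        assert sorted(once[0].units()) == sorted(twice[0].units())
        assert sorted(once[1].units()) == sorted(twice[1].units())

    def test_two_populated_action_columns_rejected(self, tmp_path):
        path = tmp_path / "review.tsv"
        path.write_text(
            "unit\tcontext\tcount\treplace_with\tremove\tinvalidate\tallow\n"
            "old\tctx\t1\t\tx\t\tx\n",
            encoding="utf-8",
        )
        with pytest.raises(MalformedRuleError, match="old"):
            RuleSet.from_tsv(path, "word")

    def test_empty_replacement_rejected(self):
        with pytest.raises(MalformedRuleError, match="remove"):
            UnitRule("wk", action=Action.REPLACE_WITH, value="")

    def test_reference_wins_on_conflict(self):
        review = RuleSet([UnitRule("wk", action=Action.REMOVE)], kind="word")
        reference = RuleSet(
            [UnitRule("wk", action=Action.REPLACE_WITH, value="week")], kind="word"
        )
        new_review, new_reference = migrate_decided(review, reference)
        assert new_reference.get("wk").action is Action.REPLACE_WITH
        assert "wk" not in new_review


def test_conservation_over_build_migrate_cycles():
    """Every observed non-default unit lives in exactly one of review/reference
    after any number of cycles."""
    items = ["8-10 wk old", "6 week", "mean 30 yr"]
    review, reference = RuleSet(kind="word"), RuleSet(kind="word")
    decisions = iter(
        [("wk", Action.REPLACE_WITH, "week"), ("old", Action.REMOVE, None),
         ("yr", Action.REPLACE_WITH, "year")]
    )
    observed = {u for u, _, _ in collect_units(items, "word")}
    for _ in range(4):
        review, reference = migrate_decided(review, reference)
        review = build_review(collect_units(items, "word"), review, reference)
        decision = next(decisions, None)
        if decision:
            unit, action, value = decision
            review.add(UnitRule(unit, action=action, value=value))
        in_review, in_reference = set(review.units()), set(reference.units())
        assert observed == in_review | in_reference
        assert not (in_review & in_reference)


def test_mass_allow_moves_matching_units_with_category():
    review = RuleSet([UnitRule("1mfd"), UnitRule("figure")], kind="word")
    review, reference = mass_allow(review, RuleSet(kind="word"),
                                   r"\d[a-z0-9]{3}", "pdb_id")
    assert reference.get("1mfd").action is Action.ALLOW
    assert reference.get("1mfd").category == "pdb_id"
    assert "figure" in review


def test_rule_tsv_round_trip(tmp_path):
    rules = RuleSet(
        [UnitRule("wk", context="8-10 wk", count=57,
                  action=Action.REPLACE_WITH, value="week"),
         UnitRule("week", action=Action.ALLOW, category="unit"),
         UnitRule("glarbl", context="glarbl item", count=2)],
        kind="word",
    )
    path = tmp_path / "rules.tsv"
    rules.to_tsv(path)
    loaded = RuleSet.from_tsv(path, "word")
    assert sorted(loaded.units()) == sorted(rules.units())
    assert loaded.get("wk").value == "week"
    assert loaded.get("week").category == "unit"
    assert not loaded.get("glarbl").decided
    assert loaded.get("glarbl").count == 2


class TestPhraseRuleset:
    def test_parse_three_slot_pattern(self):
        cats = parse_pattern_string(
            "statistical", "[statistical(0)] [number(1)] [unit(2)]"
        )
        assert cats == ("statistical", "number", "unit")

    def test_invalid_pattern_needs_no_standard_form(self, tmp_path):
        path = tmp_path / "types.tsv"
        path.write_text(
            "name\tpattern\tvalid\tstandard_form\n"
            "number\t[number(0)]\tN\t\n",
            encoding="utf-8",
        )
        (pattern,) = load_phrase_ruleset(path)
        assert pattern.valid is False and pattern.standard_form == ""

    def test_out_of_range_template_index_rejected(self):
        with pytest.raises(MalformedRuleError, match="statistical"):
            PhrasePattern("statistical", ("number", "unit"), True, "[5] [0]")

    def test_out_of_order_indices_rejected(self):
        with pytest.raises(MalformedRuleError):
            parse_pattern_string("bad", "[number(1)] [unit(0)]")

    def test_missing_file_generates_blank_ruleset(self, tmp_path):
        path = tmp_path / "types.tsv"
        assert load_phrase_ruleset(path) == []
        assert path.exists()
        assert path.read_text().startswith("name\tpattern\tvalid")

    def test_save_load_round_trip(self, tmp_path):
        patterns = [
            PhrasePattern("range", ("number", "range_indicator", "number", "unit"),
                          True, "[0]-[2] [3]"),
            PhrasePattern("number", ("number",), False),
        ]
        path = tmp_path / "types.tsv"
        save_phrase_ruleset(patterns, path)
        assert load_phrase_ruleset(path) == patterns
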