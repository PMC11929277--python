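import random

import pytest

from trinorm.rule_store import Action, RuleSet, UnitRule
from trinorm.unit_normalizer import (
    RuleConsistencyError,
    apply_char_rules,
    apply_word_rules,
)

from ._oracles import dp_levenshtein


def char_rules(*rules):
    return RuleSet(rules, kind="char")


def word_rules(*rules):
    return RuleSet(rules, kind="word")


class TestCharStage:
    def test_en_dash_replacement(self):
        rules = char_rules(UnitRule("–", action=Action.REPLACE_WITH, value="-"))
        result = apply_char_rules("20–67 years", rules)
        assert result.output == "20-67 years"
        assert result.valid and result.distance == 1

    def test_ampersand_replacement_and_lowercasing(self):
        rules = char_rules(UnitRule("&", action=Action.REPLACE_WITH, value="and"))
        result = apply_char_rules("Abstract & p. 664", rules)
        assert result.output == "abstract and p. 664"
        assert result.valid

    def test_invalidated_character_passes_item_through_unchanged(self):
        rules = char_rules(UnitRule("€", action=Action.INVALIDATE))
        result = apply_char_rules("costs 5€ total", rules)
        assert not result.valid
        assert result.output == "costs 5€ total"
        assert result.invalidating_units == ["€"]
        assert result.distance == 0

    def test_identity_when_no_rules_apply(self):
        result = apply_char_rules("6 week", char_rules())
        assert result.output == "6 week" and result.valid and result.distance == 0

    def test_unallowed_character_without_rule_fails_validation(self):
        result = apply_char_rules("6 week €", char_rules())
        assert not result.valid and "€" in result.invalidating_units
        assert result.output == "6 week €"

    def test_remove_rule_deletes_character(self):
        rules = char_rules(UnitRule("'", action=Action.REMOVE))
        result = apply_char_rules("6 week's", rules)
        assert result.output == "6 weeks" and result.distance == 1

    def test_replacement_introducing_invalidated_character_is_an_error(self):
        rules = char_rules(
            UnitRule("&", action=Action.REPLACE_WITH, value="€"),
            UnitRule("€", action=Action.INVALIDATE),
        )
        with pytest.raises(RuleConsistencyError, match="&"):
            apply_char_rules("a & b", rules)


class TestWordStage:
    def test_remove_rule_collapses_delimiter(self):
        rules = word_rules(
            UnitRule("old", action=Action.REMOVE),
            UnitRule("week", action=Action.ALLOW),
        )
        result = apply_word_rules("6-10 week old", rules, auto_allow=[r"\d+"])
        assert result.output == "6-10 week"
        assert result.valid

    def test_interior_removal_keeps_a_single_delimiter(self):
        rules = word_rules(
            UnitRule("age", action=Action.REMOVE),
            UnitRule("mean", action=Action.ALLOW),
            UnitRule("year", action=Action.ALLOW),
        )
        result = apply_word_rules("mean age = 30 year", rules, auto_allow=[r"\d+"])
        assert result.output == "mean 30 year"

    def test_replacement_preserves_delimiters(self):
        rules = word_rules(
            UnitRule("wk", action=Action.REPLACE_WITH, value="week"),
        )
        result = apply_word_rules("8-10 wk", rules, auto_allow=[r"\d+"])
        assert result.output == "8-10 week"
        assert result.valid  # replaced tokens are not re-checked this run

    def test_all_tokens_allowed_item_is_valid_and_unchanged(self):
        rules = word_rules(
            UnitRule("additional", action=Action.ALLOW),
            UnitRule("file", action=Action.ALLOW),
            UnitRule("1", action=Action.ALLOW),
        )
        result = apply_word_rules("additional file 1", rules)
        assert result.output == "additional file 1" and result.valid

    def test_undecided_token_fails_validation_and_passes_through(self):
        result = apply_word_rules("6 glarbl", word_rules(), auto_allow=[r"\d+"])
        assert not result.valid
        assert result.invalidating_units == ["glarbl"]
        assert result.output == "6 glarbl"

    def test_invalidate_rule_marks_item_invalid(self):
        rules = word_rules(UnitRule("unknown", action=Action.INVALIDATE))
        result = apply_word_rules("age unknown", rules)
        assert not result.valid and result.output == "age unknown"

    def test_protected_items_pass_through_valid(self):
        url = "https://hla-ligand-atlas.org/peptide/aaaaaqsvy"
        result = apply_word_rules(url, word_rules(), protected_prefixes=("https://",))
        assert result.valid and result.output == url and result.distance == 0


class TestStageProperties:
    def test_char_stage_is_idempotent(self, age_demo):
        rules = age_demo["char_reference"]
        for item in ["20–67 Years", "mean age = 30 years", "6 to 8-week old"]:
            once = apply_char_rules(item, rules)
            twice = apply_char_rules(once.output, rules)
            assert twice.output == once.output
            assert twice.valid == once.valid

    def test_word_stage_is_idempotent(self, age_demo):
        rules = age_demo["word_reference"]
        auto = [rx for rx, _ in age_demo["mass_allow"]]
        for item in ["6-10 week old", "8-10 wk", "mean age = 30 years",
                     "six weeks old", "6 to 8-week"]:
            once = apply_word_rules(item, rules, auto_allow=auto)
            twice = apply_word_rules(once.output, rules, auto_allow=auto)
            assert twice.output == once.output
            assert twice.valid == once.valid

    def test_distance_matches_dp_oracle_on_random_rule_applications(self):
        """Reported distances equal an independent DP oracle on 1,000
        random single-rule applications."""
        rng = random.Random(20240901)
        alphabet = "abcdef -"
        for _ in range(1000):
            item = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 20)))
            target = rng.choice("abcdef")
            kind = rng.choice(["replace", "remove"])
            if kind == "replace":
                value = "".join(rng.choice("xyz") for _ in range(rng.randint(1, 3)))
                rules = char_rules(
                    UnitRule(target, action=Action.REPLACE_WITH, value=value)
                )
            else:
                rules = char_rules(UnitRule(target, action=Action.REMOVE))
            result = apply_char_rules(
                item, rules, defaults=frozenset(alphabet + "xyz")
            )
            assert result.distance == dp_levenshtein(item, result.output)
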