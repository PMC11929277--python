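# trinorm

Rule-based three-stage normalization of free-text database fields.

Curated databases accumulate free-text fields — subject ages
("6–8 weeks old", "8-10 wks", "Six week old"), data locations inside
publications ("Fig. 2A,B,C, Fig. 6.", "PDB: 5EC1, 5EC2") — whose
*variance* (differences in representation that do not change meaning)
defeats search, aggregation and ontology mapping.  `trinorm` removes that
variance in three stages that mirror its three levels:

1. **character normalization** — lowercasing, en dash → hyphen, "&" →
   "and", invalidation of stray symbols;
2. **word normalization** — abbreviation expansion ("wk" → "week"),
   plural → singular, spelled-out numbers → numerals, filler-word removal
   ("old");
3. **phrase normalization** — each word is categorized
   (`[number(0)][unit(1)][statistical(2)]` for "6 week mean"), the
   category sequence is matched against a ruleset of named phrase-type
   patterns, and items matching a *valid* pattern are rewritten into the
   pattern's standard form (`[2]: [0] [1]` → "mean: 6 week").

The tool is deliberately **user-dependent** rather than predictive: each
stage surveys the dataset's distinct text units into a *review* TSV, the
user records an action decision per unit — `replace_with`, `remove`,
`invalidate`, or `allow` — and on the next run decided rows migrate to a
*reference* TSV, the persistent rule bank.  Validity is explicit at every
stage: an item passes the character/word stage when only allowed units
remain, and the phrase stage when it matches a pattern flagged valid
(unitless ages like "8–10" are *intentionally* caught by invalid
patterns).  Invalid items are carried through unchanged, never dropped.

An accessory **list splitter** runs between the word and phrase stages for
list-like fields, expanding distributed heads and letter suffixes
("Fig. 2A,B,C, Fig. 6." → "fig. 2a", "fig. 2b", "fig. 2c", "fig. 6") with
per-segment index bookkeeping.  Levenshtein distances are logged per item
at the character and word stages, and split phrase count / phrase validity
rate once per original item.

## Worked example

`init-demo` writes a synthetic messy corpus (with ground truth), the
bundled demonstration rulesets and a config; `run-all` runs every stage:

```sh
trinorm init-demo --dataset age --workdir rd --n-items 200 --seed 1
trinorm run-all --config rd/age_config.yaml
```

```
trinorm.pipeline INFO stage=char dataset=age items=200 valid=200 invalid=0 new_review_rows=0 seed=1
trinorm.pipeline INFO stage=word dataset=age items=200 entered=200 valid=200 invalid=0 new_review_rows=0 seed=1
trinorm.pipeline INFO stage=phrase dataset=age items=200 entered=200 valid=177 invalid=23 segments=200 seed=1
trinorm.pipeline INFO metric summary:
  char_distance: mean=0.08 sd_pop=0.2713 sd_sample=0.272 n=200
  word_distance: mean=1.27 sd_pop=1.867 sd_sample=1.872 n=200
  split_phrase_count: mean=1 sd_pop=0 sd_sample=0 n=200
  phrase_validity_rate: mean=0.885 sd_pop=0.319 sd_sample=0.3198 n=200
```

Each log line reports how many items entered the stage (later stages only
process items valid at every earlier stage) and how many passed its
validation; here 177/200 items end phrase-valid and the other 23 are
intentionally ambiguous unitless numbers and ranges matched by invalid
patterns.  `rd/age_phrase_output.tsv` traces every item:

```
original            word_normalized     cat_string                          valid  phrase_normalized
3-5 hour old        3-5 hour            [number(0)][number(1)][unit(2)]     1      3-5 hour
36–45 weeks         36-45 week          [number(0)][number(1)][unit(2)]     1      36-45 week
average: 47.8 yr    average: 47.8 year  [statistical(0)][number(1)][unit(2)]  1    average: 47.8 year
82 month old        82 month            [number(0)][unit(1)]                1      82 month
```

The same flow drives the library API:

```python
from trinorm import demo_rulesets, normalize_phrase

demo = demo_rulesets("age")
result = normalize_phrase("6 week mean", demo["word_reference"],
                          demo["phrase_ruleset"])
print(result.cat_string)   # [number(0)][unit(1)][statistical(2)]
print(result.output)       # mean: 6 week
```

All output surface forms are lowercase: uppercase letters sit outside the
default always-valid character set and case is treated as pure character
variance.

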