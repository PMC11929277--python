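# Methods

## The normalization model

`trinorm` treats a free-text field as a list of independent *data items*
and removes representational variance in three ordered stages, each with an
explicit validity verdict.  The underlying model of text is deliberately
minimal: an item is a sequence of characters; a *word* is a maximal run of
non-delimiter characters; a *phrase* is the item's sequence of words.  No
linguistic machinery (stemming, sentence structure, embeddings) is used —
every transformation is a user-authored rule, which is what makes the tool
suitable for fields where synonym substitution or probabilistic correction
is unacceptable.

**Character stage.**  Letters are lowercased (case is treated as pure
character variance; uppercase letters are outside the default always-valid
set), then per-character rules apply: `replace_with` substitutes,
`remove` deletes, `invalidate` fails the item, `allow` extends the valid
alphabet.  An item is valid when every remaining character is in the
always-valid default set (a–z, 0–9, space, `. , - : ; ( ) /`;
configurable) or allowed by rule.

**Word stage.**  Only character-valid items enter.  Tokens are matched
whole and case-sensitively against word rules with the same four actions.
Replacements keep the surrounding delimiter runs; removals collapse the
doubled delimiter (the run vanishes at a string boundary, so
"6-10 week old" → "6-10 week").  An item is valid when every untouched
token is allowed; replacement output is not re-scanned within a run — new
units it introduces surface in the next review cycle.

**Phrase stage.**  Only character- and word-valid items enter.  Each word
receives a category (word-reference `category` column, then built-in
auto-categorizers, else `unknown`), the category sequence is serialized as
e.g. `[number(0)][unit(1)][statistical(2)]`, and matched — exactly, first
match in file order — against the phrase-type ruleset.  Items matching a
pattern flagged valid are rewritten into its standard-form template
(`[2]: [0] [1]` → "mean: 6 week"); original inter-word delimiters are
discarded, the template supplies all output separators.  Items matching an
invalid pattern (unitless numbers and ranges, whose meaning is ambiguous)
or no pattern fail phrase validation.

**Invariants.**  Stage-invalid items pass through byte-identical, so
nothing is lost for re-curation.  Each stage is a fixed point: re-applying
it to its own output changes nothing.  For phrase rules this requires that
every standard form's own category sequence be matched by some pattern;
`lint_ruleset` checks this statically (templates containing literal words
are flagged as uncheckable) and also flags duplicate sequences and dropped
token indexes.  Dropping an index is sometimes intended — the range
template `[0]-[2] [3]` deliberately drops the `range_indicator` token.

## The review/reference cycle

Every run surveys the dataset's distinct units (characters: all except the
always-valid defaults; words: all), appends unseen units to the *review*
TSV with a context sample (distinct containing items joined by " | ",
capped at 300 characters) and a total occurrence count, and migrates rows
in which the user has filled exactly one action column into the
*reference* TSV.  Conservation holds by construction: each observed
non-default unit lives in exactly one of review/reference, and migration
is idempotent.  On a unit appearing in both files, the reference rule wins
with a logged warning.  A row with two populated action columns, or a
`replace_with` with empty text, is rejected naming the offending unit.

Open-ended unit families (plain numbers, sub-panel letters, PDB-style
four-character identifiers, S-numbers) cannot be enumerated in a finite
reference file.  They are handled by **mass-allow** regexes, configured
per dataset: observed matching units are bulk-decided into the reference
as allow rules (optionally with a category), and the same regexes count
as allowed at validation time so that rule state remains a true fixed
point (e.g. the output "6 week" of the replacement "six" → "6" stays
valid on a re-run even though "6" itself was never surveyed).

## The list splitter

List-like data-location items are split between the word and phrase
stages so each segment can match a simple pattern.  Elements are separated
by commas, semicolons, standalone "and" and "&"; a comma directly between
two digits is numeric punctuation ("11,782"), not a separator.  An element
ending in a reference token (number with optional letter suffix, S-number,
or PDB-style id) sets the current *head* (its preceding words), which
distributes over following bare references; bare single letters attach to
the current head and number ("2A,B,C" → "2a", "2b", "2c", lowercased); an
element with no trailing reference stands alone and resets the head.
Protected-prefix items (URLs) are never split, and ranges ("Figs. 1-4")
are not expanded — flagged for review rather than guessed at.  Segments
carry an original index and a split index; per-original metrics (split
phrase count, validity rate, distances) are written exactly once, on the
first segment row, so corpus means are not skewed by the row-count
increase.  Splitting a segment again is a no-op.

## Metrics

Levenshtein distance (unit-cost, via the `edlib` alignment library,
cross-checked in the tests against an independently coded full
dynamic-programming matrix) is recorded per item at the character stage
(original vs output) and word stage (character output vs word output).  No
distance is tracked at the phrase stage, where benign word-order changes
produce large, meaningless scores — "18 years average" vs
"average 18 years" is distance 14.  Stage validity rates use as
denominator the items *entering* that stage.  Summaries report means with
both population and sample standard deviations, since convention differs
between tools.

## Synthetic corpora

The fixture generators emulate the two motivating field types with known
ground truth — the canonical form (age), the canonical segment list
(data-location), or the INVALID verdict for intentionally ambiguous items
(unitless numbers/ranges, bare location numbers).  Noise classes are
sampled independently per item: en dashes, abbreviated and plural units,
spelled-out numbers, "N to M" range phrasing, leading capitals, "old"/"age"
filler, alternative statistical arrangements, list-head elision, letter
suffixes, uppercase URL paths and PDB ids.  Default rates (e.g. plural
units 0.35, abbreviations 0.15, en dash 0.15, URL fraction 0.30, mean list
length 3) were chosen once to resemble a messy curated field in which most
items carry one or two variance classes; identical spec and seed reproduce
the corpus exactly, and zero noise reproduces the canonical forms.

What the generators do *not* emulate: the frequency skew of real curated
fields (a handful of values covering most rows), misspellings beyond the
fixed abbreviation tables, nested or malformed lists, and encoding
artifacts.  Passing the round-trip test therefore shows that the engine
applies a covering ruleset correctly and deterministically — not that the
bundled demonstration rules would cover an arbitrary real dataset, whose
rule-building remains a user task by design.  Corpus-level validity
percentages of the original curated age and data-location datasets
(99.97/98.06/83.81 % and 99.99/98.46/97.95 % across the three stages)
require those full datasets and their complete rule files; with them on
disk the pipeline can be pointed at the TSVs as an integration check, but
they are not part of the test suite.

## Numerical and design choices

- Default delimiters: space, tab, hyphen, comma, period, colon, semicolon,
  parentheses, square brackets, slash, equals; configurable per dataset.
  `.` and `,` directly between digits are part of the number token.
- Output surface forms are all-lowercase, including canonical display
  words like "figure": reintroducing capitalized display forms would make
  the character stage non-idempotent for no informational gain.
- Rule order within a stage is fixed (replace, remove, invalidate check,
  allow check) for determinism; replacements are single-pass,
  non-overlapping, left-to-right.
- The pdb-id auto-categorizer (opt-in per dataset) takes priority over the
  number categorizer only for tokens containing a letter; all-digit
  four-character tokens stay numbers, and the demonstration ruleset
  carries a separate valid `[pdb][number]` pattern for all-digit ids.
- Unit counts in review files are total occurrences, not distinct-item
  counts.  Any non-empty cell marks a remove/invalidate/allow decision.
- Degenerate inputs: an empty or all-delimiter item has no tokens and
  passes the word stage unchanged; an empty corpus is an error for
  summary statistics; a missing phrase ruleset file is created blank and
  every item then fails phrase validation with a logged warning.
- Problem sizes in the test suite (corpora of 150–1,000 synthetic items,
  10,000 random string pairs for the distance cross-check) keep the full
  suite in the low seconds while exercising every stage end to end.

## Known limitations

- Comma-separated digit runs without spaces ("Figs. 2,3,4") parse as one
  number token; the motivating datasets print spaces after list commas.
- The splitter grammar handles head distribution and letter suffixes but
  not nested or mixed lists beyond it; unexpected shapes pass through as
  single segments and surface in review rather than being guessed.
- Word matching is exact: misspellings become review rows, never
  auto-corrections.  This is the intended trade-off of a user-dependent
  tool.
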