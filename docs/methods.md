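# Methods

## The model of a real-word error

`clinspell` treats a real-word error as a single-token substitution in a
normalized sentence, produced by a small edit (character insertions and
deletions only) that happens to land on another attested word. This
yields three structural commitments that run through the whole package:

1. **One error per sentence.** Every generated record differs from its
   correct counterpart at exactly one token position, recorded in the
   metadata. Multi-error sentences are out of scope.
2. **Lexicon gate.** A rule's candidate becomes an error only if it is
   attested in the corpus-derived lexicon (exact, case-sensitive lookup;
   capitalized tokens are gated on their lower-cased form and the
   initial capital is restored on the replacement). This is what makes
   the error *real-word* rather than a non-word typo.
3. **Indel geometry.** Because errors are built from insertions and
   deletions, the natural error-to-original distance is the
   Levenshtein distance restricted to those operations,
   `d(a, b) = |a| + |b| − 2·LCS(a, b)`. Accented characters are
   distinct (`'a' ≠ 'á'`), so e.g. `d(peleaba, peleábamos) = 5`.
   Generation enforces `d ≤ 3` for the gender, number, gender-number,
   homophone and suggestion groups and `d ≤ 6` for subject-verb
   concordance (person swaps can rewrite long terminations).

## Preprocessing

Sentences are split by a rule-based splitter (terminator `. ? !`
followed by whitespace and a capital letter or digit; newlines always
split). Sentence-initial semicolons — an artifact of clause-splitting —
are stripped. Normalization masks every maximal digit run with a
configurable constant token (default `NUM`; runs in `120/80` mask
independently), turns every character that is neither a letter nor
retained punctuation into a space, splits the retained punctuation
`. , ; : ? !` into standalone tokens, and preserves case (lower-case
sentence starts are themselves a real-word-error phenomenon, so
true-casing would destroy signal). Normalization is idempotent.
The length filter keeps sentences with `min < length ≤ max`
(defaults 5 and 40); small corpora are typically not filtered
(`enabled=False`).

The tension between "non-alphanumeric symbols become spaces" and
"punctuation is kept as tokens" is resolved by whitelisting sentence
punctuation: parentheses, slashes, quotes, `%` and the like are deleted
(become spaces), the six sentence marks survive as tokens.

## Rule groups

* **Gender.** Eleven masculine suffixes (`-ero -ano -ado -ino -ido -ico
  -ito -oso -ario -ento -olo`) with their regularly derived feminine and
  plural counterparts, both directions, longest suffix first. The
  deliberately conservative suffix list (rather than bare `-o`/`-a`)
  avoids firing on gender-invariant words like *casa*.
* **Number.** Singular endings `-o -e -a` pluralize with `-s`,
  `-d -n -l -j -r` with `-es`; plural endings `-os -es -as` reverse the
  rules (`-es` tries the consonant reading `virtudes → virtud` before
  the vowel reading `aeronaves → aeronave`).
* **Gender-number.** Composition in a fixed order: singular words flip
  gender then pluralize; plural words singularize then flip gender.
* **Homophone.** `b↔v` and `ll↔y` at every occurrence, silent-`h`
  deletion word-initially and after `n`/`s`, and the inverse
  insertions. Insertions only apply before a vowel — `h` is only silent
  pre-vocalically, and unconstrained insertion would generate
  unpronounceable non-words like `hdato`.
* **Suggestion.** The internal suggester ranks lexicon entries within
  indel distance 3 by (distance, frequency descending, alphabetical) and
  picks the first candidate that none of the other five groups could
  have produced, so this group contributes genuinely new error shapes
  (including accent-only errors such as `calle → callé`). An external
  spell-checker backend can replace the suggester behind the same
  contract; suggestion lookups are memoized per word.
* **Concordance.** A word is recognized as a regular verb if its ending
  matches a listed termination (3 tenses × 2 moods × 6 persons per
  conjugation class, longest-suffix-first with ties broken in table
  order) *and* the reconstructed infinitive is in the lexicon; failing
  that, it is matched against the full conjugation of the auxiliary
  *haber*. The error swaps the person uniformly at random within the
  same tense and mood. Spanish syncretism (1st/3rd person imperfect and
  subjunctive forms coincide) means the six terminations of a cell are
  not always distinct; swaps that reproduce the same surface form are
  excluded. "Past" is the imperfect paradigm.

The sentence driver scans tokens left to right, skipping punctuation,
the number mask and a packaged skip list of determiners, prepositions
and other high-frequency function words (which would otherwise absorb
most errors and kill variability). At the first token with at least one
admissible candidate it applies one rule — chosen uniformly at random
when a seeded generator is supplied, first-in-order otherwise — and
stops.

## Compilation strategies and splits

Strategy 1 tries all six groups on every sentence (≤ 6 error records)
and always appends one identity pair per sentence, bounding output size
in `[n, 7n]`. Strategy 2 shuffles the group order per sentence and
keeps the first success, emitting exactly `n` records with the identity
pair only as a fallback. Both are deterministic given the seeded
generator. Balance between types is intended, not exact: homophone
opportunities are rarer than number opportunities, and the compiled
type counts reflect that.

Test splits are stratified by error type (`n_test // n_types` records
per type, truncated to the smallest type count when infeasible) and
exclude identity records by default; validation is sampled uniformly
from the remainder. Splits operate on records; an optional grouped
split by target sentence is not enabled by default.

## Post-processing and evaluation

Corrector output is aligned to the source positionally: `<unknown>`
placeholders and predictions farther than the threshold fall back to
the source token, positions past the prediction's end are copied from
the source, so output length always equals source length. The
threshold comparison is inclusive (`≤`, default 6): a strict `<` at 6
would make distance-6 concordance corrections unreachable; a strict
mode is available. One global threshold is used at inference time
because the error type of an unseen sentence is unknown; the per-type
caps (3/6) are generation-time guarantees, not runtime switches.

Scoring is token-level by default, using the generator's recorded error
position: an error is *corrected* iff the output token there equals the
gold token; any output token differing from both source and gold at its
position is one *bad correction* (identity sentences can only
contribute bad corrections). `R`, `P` and `F0.5 = 1.25·P·R/(0.25·P+R)`
are percentages; any 0/0 ratio is defined as 0. A strict sentence-level
mode (corrected iff output equals the gold sentence exactly) is provided
for sensitivity analysis. Rows recomputed from reported (R, P) pairs
agree with their F0.5 to ±0.05 — the residue of two-decimal rounding of
the inputs.

## Synthetic corpus generator

The generator emulates short clinical-report Spanish: template clauses
(subject–verb–object, impersonal *se*, perfect tenses with *haber*,
copular descriptions, first-person-plural report style) filled from a
packaged mini-lexicon of clinical-register lemmas (paciente, ecografía,
sangrado, conservado, realizar, …) with full agreement in gender,
number and verb person. Sentences are 5–20 tokens, pre-normalized
(fixed points of the normalizer), and deterministic under a seed.

Design properties the tests rely on:

* **Closure.** Every inflectional paradigm is closed under the rules —
  all four gender/number forms of adjectives and person nouns, both
  noun numbers, and all 36 regular forms of each verb are in the
  mini-lexicon — so the lexicon gate cannot starve any group.
* **Homophone seeding.** Pairs whose members are both real words
  (uso/huso, hecho/echo, tubo/tuvo, a/ha, …) appear explicitly.
* **Coverage.** On the default templates all six groups fire well
  below 1,000 sentences (`COVERAGE_N`).

What the generator does *not* emulate: real clinical semantics,
misspellings already present in source text, OCR noise, vocabulary at
corpus scale (hundreds of forms, not hundreds of thousands), irregular
verbs, gender-exception nouns, clitics. Consequently, passing tests
demonstrate the correctness of the machinery — rules, gates, distance
caps, compilation bookkeeping, metrics — not corrector performance on
real clinical text, where lexical coverage and error diversity are far
larger.

The bigram-vote frequency baseline scores each token's candidate set
(the token plus every real-word form the six groups can reach from it)
by summed left+right bigram counts from a training corpus and replaces
the token only on a strict win (ties keep the source). It exists to
exercise the evaluation path end-to-end with a non-trivial,
deterministic corrector; it is not a serious correction method.

## Problem sizes and numerical choices

The distance-bound and coverage checks run on a 10,000-sentence
synthetic compilation (~40,000 cap-3 errors, ~8,000 concordance errors)
— large enough that every rule and template interacts, while a full
suite run stays in tens of seconds. The indel implementation
(prefix/suffix trimming + one-row LCS dynamic program) is verified
exhaustively against an independent brute-force insert/delete edit
search on all string pairs of length ≤ 6 over a 3-letter alphabet, and
property-tested as a metric. All randomness flows through injected
`random.Random` instances; nothing reads global random state.

## Known limitations

* Only regular verb morphology; irregular and stem-changing verbs are
  recognized at most accidentally.
* Accent-shifting inflections (lesión/lesiones, riñón/riñones) are not
  modeled by the number rules; such candidates simply fail the lexicon
  gate.
* The suggestion group's ranking is a frequency heuristic, not a
  phonetic or keyboard model; with an external spell checker the
  suggestion distribution changes.
* The positional alignment in post-processing assumes the corrector
  roughly preserves token order; heavily re-segmented output degrades
  to source-token fallback.
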