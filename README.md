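# clinspell

Synthesis, compilation and scoring of **real-word spelling errors** in
Spanish clinical text.

A real-word error is a misspelling whose result is itself a valid word —
*unida* for *unido*, *ha* for *a*, *llevas* for *llevan* — so no
dictionary lookup can catch it; only context can. Training a contextual
corrector needs large parallel corpora of (erroneous, correct) sentences,
which do not exist for clinical Spanish. `clinspell` manufactures them:
it plants rule-based real-word errors in clean text, compiles the
line-parallel datasets a sequence-to-sequence corrector trains on,
post-processes corrector output, and scores corrections with the standard
error-correction metrics. It is aimed at clinical-NLP practitioners
building or evaluating Spanish text correctors.

## What it does

**Error synthesis.** Six rule groups each turn one correct word into a
different *real* word (candidates must be attested in a corpus-derived
lexicon):

| group | example | mechanism |
|---|---|---|
| gender | unido → unida | common morphological suffixes (-ero, -ado, -ido, -oso, …) |
| number | aeronave → aeronaves | singular/plural endings (-o/-e/-a + s, consonant + es) |
| gender-number | sinuosos → sinuosa | both flips composed |
| homophone | uso → huso | b/v, ll/y swaps and the silent h |
| suggestion | calle → callé | first ranked lexicon suggestion not reachable by the other groups |
| concordance | llevan → llevas | person swap of a regular verb within its tense and mood |

Every error differs from its original only by character insertions and
deletions: at most 3 for the first five groups and at most 6 for
subject-verb concordance.

**Dataset compilation.** Strategy 1 emits up to one erroneous sentence
per group per correct sentence plus the correct sentence itself (identity
pair); strategy 2 emits exactly one sentence per input, trying the groups
in random order. Splits are stratified so the test set is balanced
across error types.

**Post-processing.** The insert/delete-only Levenshtein distance
`d(a, b) = |a| + |b| − 2·LCS(a, b)` gates corrector output: `<unknown>`
tokens and predictions more than a threshold (default 6) away from the
source token fall back to the source.

**Evaluation.** With `Corrected` fixed errors, `Total` planted errors
and `Bad` tokens changed to something that is neither source nor gold:

```
R = Corrected / Total      P = Corrected / (Corrected + Bad)
F0.5 = 1.25·P·R / (0.25·P + R)
```

reported per error type and overall, as percentages.

A packaged synthetic clinical-Spanish corpus generator (template
sentences over a ~300-lemma clinical mini-lexicon, closed under the
inflection rules) makes the whole pipeline runnable with no external
data, and reference correctors (oracle, identity, a bigram-vote
frequency baseline) anchor the metrics.

## Worked example

```python
import random
import clinspell as cs

corpus = cs.generate_corpus(5000, seed=42)       # synthetic clinical Spanish
lex = cs.mini_lexicon(corpus)                    # real-word lexicon
groups = cs.build_rule_groups(lex)
skip = cs.load_skip_list()

train, held_out = corpus[:4000], corpus[4000:]
ds = cs.compile_strategy2(held_out, groups, lex, skip, random.Random(43))
errors = ds.error_records()
rec = errors[0]
print("source:", rec.source.text)
print("target:", rec.target.text)
print("type:", rec.error_type, "| distance:", rec.distance)

corrector = cs.FrequencyCorrector(train, groups, lex)   # bigram baseline
raw = corrector(errors)
cfg = cs.PostprocessConfig(threshold=6)
fixed = [cs.resolve_prediction(r.source, list(p.tokens), cfg)
         for r, p in zip(errors, raw)]
print(cs.report(errors, fixed).to_frame().to_string(index=False))
```

prints

```
source: Responda una cirujana sin molestias .
target: Respondamos una cirujana sin molestias .
type: concordance | distance: 3
  error_type  total  corrected  bad     R     P  F0.5
 concordance    172        117  167 68.02 41.20 44.72
       genre    181        123  227 67.96 35.14 38.90
genre_number    161        105  190 65.22 35.59 39.15
   homophone     69         66   60 95.65 52.38 57.59
      number    222        218  327 98.20 40.00 45.38
  suggestion    195         77  213 39.49 26.55 28.41
     overall   1000        706 1184 70.60 37.35 41.24
```

Each of the 1000 held-out sentences carries exactly one planted error
(strategy 2). The generator swapped the verb person *respondamos* →
*responda*, an indel distance of 3. The bigram baseline recovers 70.6%
of errors (recall) but also corrupts many clean tokens, so precision and
the precision-weighted F0.5 are much lower — exactly the trade-off F0.5
is designed to expose. Homophone and number errors, whose corrections
dominate their contexts, are recovered best; suggestion errors, which by
construction evade the morphological rules, are hardest.

The same pipeline is available from the shell: `clinspell preprocess`,
`build-lexicon`, `generate`, `compile`, `correct-postprocess`,
`evaluate`, `simulate` (see `clinspell --help`).

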