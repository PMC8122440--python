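"""Rule-based synthesis of real-word errors in Spanish sentences.

Six rule groups each turn one correct word into a different real word:

* ``genre`` — flip grammatical gender on common morphological suffixes
  (``unido`` -> ``unida``);
* ``number`` — flip grammatical number on common word endings
  (``aeronave`` -> ``aeronaves``);
* ``genre_number`` — flip both in sequence (``sinuosos`` -> ``sinuosa``);
* ``homophone`` — exploit sound-identical spellings, b/v, ll/y and the
  silent h (``uso`` -> ``huso``);
* ``suggestion`` — take the first spell-checker-style suggestion not
  producible by the other groups (``calle`` -> ``callé``);
* ``concordance`` — swap a regular verb's person within its tense and
  mood, breaking subject-verb agreement (``llevan`` -> ``llevas``).

A candidate only becomes an error if it is attested in the corpus-derived
lexicon (so it is a *real* word) and lies within the group's indel
distance cap: 3 for all groups except subject-verb concordance, whose
person swaps can differ by up to 6 edit operations.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Sequence

import yaml

from .lexicon import ConjugationTables, Lexicon, identify_verb
from .postprocess import indel_distance
from .preprocess import DEFAULT_NUMBER_MASK, RETAINED_PUNCTUATION, Sentence

GENRE = "genre"
NUMBER = "number"
GENRE_NUMBER = "genre_number"
HOMOPHONE = "homophone"
SUGGESTION = "suggestion"
CONCORDANCE = "concordance"

#: Canonical group order (also the strategy-1 application order).
ERROR_TYPES = (GENRE, NUMBER, GENRE_NUMBER, HOMOPHONE, SUGGESTION, CONCORDANCE)

#: Max indel distance between error and original, by error type.
DISTANCE_CAPS = {t: 3 for t in ERROR_TYPES}
DISTANCE_CAPS[CONCORDANCE] = 6


def _load_rules() -> dict:
    with resources.files("clinspell.data").joinpath("rules.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return yaml.safe_load(fh)


def load_skip_list() -> frozenset[str]:
    """Packaged skip list: determiners, prepositions and other function
    words the generator never plants errors on."""
    with resources.files("clinspell.data").joinpath("skiplist.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return frozenset(yaml.safe_load(fh)["skip_list"])


_RULES = _load_rules()

# -- genre ------------------------------------------------------------------

def _genre_pairs(suffixes: Sequence[str]) -> list[tuple[str, str]]:
    """Ordered (match-suffix, replacement) pairs: plural before singular
    (longest match first), masculine->feminine before the inverse."""
    pairs: list[tuple[str, str]] = []
    for masc in suffixes:
        fem = masc[:-1] + "a"
        pairs.append((masc + "s", fem + "s"))
        pairs.append((fem + "s", masc + "s"))
    for masc in suffixes:
        fem = masc[:-1] + "a"
        pairs.append((masc, fem))
        pairs.append((fem, masc))
    return pairs


_GENRE_PAIRS = _genre_pairs(_RULES["genre_suffixes"])


def genre_candidates(word: str) -> list[str]:
    """All gender-flipped forms of ``word`` under the suffix table."""
    out: list[str] = []
    for suffix, repl in _GENRE_PAIRS:
        if len(word) > len(suffix) and word.endswith(suffix):
            cand = word[: -len(suffix)] + repl
            if cand != word and cand not in out:
                out.append(cand)
    return out


# -- number -----------------------------------------------------------------

_VOWEL_ENDINGS = tuple(_RULES["number"]["vowel_endings"])
_CONSONANT_ENDINGS = tuple(_RULES["number"]["consonant_endings"])
_PLURAL_ENDINGS = tuple(_RULES["number"]["plural_endings"])


def number_candidates(word: str) -> list[str]:
    """Pluralized / singularized forms of ``word``.

    Plural -> singular first: strip ``-es`` after a listed consonant, else
    strip ``-s`` after a listed vowel.  Singular -> plural: add ``-s``
    after a listed vowel, ``-es`` after a listed consonant.
    """
    out: list[str] = []

    def _add(c: str) -> None:
        if c and c != word and c not in out:
            out.append(c)

    for plural in _PLURAL_ENDINGS:
        if len(word) > len(plural) and word.endswith(plural):
            if plural == "es" and word[-3] in _CONSONANT_ENDINGS:
                _add(word[:-2])  # virtudes -> virtud
            if word[-2] in _VOWEL_ENDINGS:
                _add(word[:-1])  # aeronaves -> aeronave, casos -> caso
    if len(word) > 1:
        if word.endswith(_VOWEL_ENDINGS):
            _add(word + "s")
        elif word.endswith(_CONSONANT_ENDINGS):
            _add(word + "es")
    return out


def _is_plural_form(word: str) -> bool:
    return any(
        len(word) > len(p) and word.endswith(p) for p in _PLURAL_ENDINGS
    )


# -- genre-number -----------------------------------------------------------

def genre_number_candidates(word: str) -> list[str]:
    """Forms with both gender and number flipped.

    Singular words: gender first, then pluralize.  Plural words: to
    singular first, then flip gender — so ``sinuosos`` -> ``sinuoso`` ->
    ``sinuosa`` and ``abandonado`` -> ``abandonada`` -> ``abandonadas``.
    """
    out: list[str] = []
    if _is_plural_form(word):
        for sg in number_candidates(word):
            if len(sg) >= len(word):
                continue  # only the singularizing direction
            for cand in genre_candidates(sg):
                if cand != word and cand not in out:
                    out.append(cand)
    else:
        for flipped in genre_candidates(word):
            for cand in number_candidates(flipped):
                if len(cand) <= len(flipped):
                    continue  # only the pluralizing direction
                if cand != word and cand not in out:
                    out.append(cand)
    return out


# -- homophone --------------------------------------------------------------

_SWAPS = [tuple(pair) for pair in _RULES["homophone"]["swaps"]]
_H_AFTER = tuple(_RULES["homophone"]["h_after"])
_VOWELS = set("aeiouáéíóúü")


def homophone_candidates(word: str) -> list[str]:
    """Sound-preserving respellings of ``word``.

    Substring swaps (ll/y, b/v) at every occurrence, silent-h deletion
    (word-initial or after n/s) and the inverse h insertions.
    """
    out: list[str] = []

    def _add(c: str) -> None:
        if c and c != word and c not in out:
            out.append(c)

    for a, b in _SWAPS:
        for src, dst in ((a, b), (b, a)):
            start = word.find(src)
            while start != -1:
                _add(word[:start] + dst + word[start + len(src):])
                start = word.find(src, start + 1)
    # silent h removal
    if word.startswith("h"):
        _add(word[1:])
    for i, ch in enumerate(word[:-1]):
        if ch in _H_AFTER and word[i + 1] == "h":
            _add(word[: i + 1] + word[i + 2:])
    # silent h insertion (inverse rules); h is only silent before a vowel
    if word[:1] in _VOWELS:
        _add("h" + word)
    for i, ch in enumerate(word[:-1]):
        if ch in _H_AFTER and word[i + 1] in _VOWELS:
            _add(word[: i + 1] + "h" + word[i + 1:])
    return out


# -- concordance ------------------------------------------------------------

def concordance_candidates(
    word: str, tables: ConjugationTables, lex: Lexicon
) -> list[str]:
    """All person swaps of ``word`` within its tense and mood.

    Empty when ``word`` is not recognized as a regular conjugated form
    (or a form of ``haber``).  Swaps that reproduce the same surface form
    (persons sharing a termination) are dropped.
    """
    analysis = identify_verb(word, tables, lex)
    if analysis is None:
        return []
    if analysis.is_haber:
        row = tables.haber[analysis.tense][analysis.mood]
        return [f for f in row if f != word]
    stem = word[: -len(analysis.termination)]
    row = tables.terminations(
        analysis.conjugation_class, analysis.tense, analysis.mood
    )
    out: list[str] = []
    for term in row:
        cand = stem + term
        if cand != word and cand not in out:
            out.append(cand)
    return out


def apply_concordance(
    word: str,
    tables: ConjugationTables,
    lex: Lexicon,
    rng: random.Random,
    distance_cap: int = DISTANCE_CAPS[CONCORDANCE],
) -> str | None:
    """Swap the person of a regular verb form, drawn uniformly among the
    other persons of the same tense and mood; ``None`` if the word is not
    a recognized verb form or the drawn swap exceeds the distance cap."""
    cands = concordance_candidates(word, tables, lex)
    if not cands:
        return None
    cand = rng.choice(cands)
    return cand if indel_distance(word, cand) <= distance_cap else None


# -- suggestion -------------------------------------------------------------

def apply_suggestion(
    word: str,
    lex: Lexicon,
    tables: ConjugationTables | None = None,
    max_distance: int = DISTANCE_CAPS[SUGGESTION],
) -> str | None:
    """First ranked suggestion that no other rule group could produce.

    Candidates producible by the gender, number, gender-number, homophone
    or concordance groups are excluded so that the suggestion group adds
    genuinely new error types.
    """
    excluded = set(genre_candidates(word))
    excluded.update(number_candidates(word))
    excluded.update(genre_number_candidates(word))
    excluded.update(homophone_candidates(word))
    if tables is not None:
        excluded.update(concordance_candidates(word, tables, lex))
    suggestions = lex.suggest(
        word, max_distance=max_distance, exclusions=[excluded.__contains__]
    )
    return suggestions[0] if suggestions else None


# -- simple apply_* wrappers ------------------------------------------------

def _first_admissible(
    cands: list[str], lex: Lexicon | None, word: str
) -> str | None:
    if lex is not None:
        cands = [c for c in cands if c in lex and c != word]
    return cands[0] if cands else None


def apply_genre(word: str, lex: Lexicon | None = None) -> str | None:
    """Gender flip; with a lexicon, the first real-word candidate."""
    return _first_admissible(genre_candidates(word), lex, word)


def apply_number(word: str, lex: Lexicon | None = None) -> str | None:
    """Number flip; with a lexicon, the first real-word candidate."""
    return _first_admissible(number_candidates(word), lex, word)


def apply_genre_number(word: str, lex: Lexicon | None = None) -> str | None:
    """Combined gender+number flip."""
    return _first_admissible(genre_number_candidates(word), lex, word)


def apply_homophone(word: str, lex: Lexicon | None = None) -> str | None:
    """Homophone respelling; with a lexicon, the first real-word candidate."""
    return _first_admissible(homophone_candidates(word), lex, word)


# -- rule groups and the sentence-level driver ------------------------------


@dataclass
class RuleGroup:
    """One error type: a candidate generator plus its distance cap."""

    error_type: str
    candidates: Callable[[str], list[str]]
    distance_cap: int

    def admissible(self, word: str, lex: Lexicon) -> list[str]:
        """Candidates that are real words within the distance cap."""
        out = []
        for cand in self.candidates(word):
            if (
                cand != word
                and cand in lex
                and indel_distance(word, cand) <= self.distance_cap
            ):
                out.append(cand)
        return out


def build_rule_groups(
    lex: Lexicon,
    tables: ConjugationTables | None = None,
    suggestion_cache: dict | None = None,
) -> dict[str, RuleGroup]:
    """The six standard rule groups bound to a lexicon.

    Suggestion lookups scan the whole lexicon and are memoized per word
    (``suggestion_cache`` may be shared across groups/compilations).
    The concordance group exposes every admissible person swap; the random
    draw happens in :func:`generate_error`.
    """
    tables = tables or ConjugationTables()
    cache: dict[str, list[str]] = (
        suggestion_cache if suggestion_cache is not None else {}
    )

    def _suggestion(word: str) -> list[str]:
        if word not in cache:
            first = apply_suggestion(word, lex, tables)
            cache[word] = [first] if first else []
        return cache[word]

    return {
        GENRE: RuleGroup(GENRE, genre_candidates, DISTANCE_CAPS[GENRE]),
        NUMBER: RuleGroup(NUMBER, number_candidates, DISTANCE_CAPS[NUMBER]),
        GENRE_NUMBER: RuleGroup(
            GENRE_NUMBER, genre_number_candidates, DISTANCE_CAPS[GENRE_NUMBER]
        ),
        HOMOPHONE: RuleGroup(
            HOMOPHONE, homophone_candidates, DISTANCE_CAPS[HOMOPHONE]
        ),
        SUGGESTION: RuleGroup(SUGGESTION, _suggestion, DISTANCE_CAPS[SUGGESTION]),
        CONCORDANCE: RuleGroup(
            CONCORDANCE,
            lambda w: concordance_candidates(w, tables, lex),
            DISTANCE_CAPS[CONCORDANCE],
        ),
    }


@dataclass(frozen=True)
class ErrorRecord:
    """One planted error: a (source, target) sentence pair differing at
    exactly one token, with bookkeeping for evaluation."""

    source: Sentence
    target: Sentence
    error_type: str
    token_index: int
    original_token: str
    error_token: str
    distance: int


def _restore_case(original: str, replacement: str) -> str:
    if original[:1].isupper() and replacement:
        return replacement[0].upper() + replacement[1:]
    return replacement


def generate_error(
    target: Sentence,
    group: RuleGroup,
    lex: Lexicon,
    skip_list: Iterable[str] = (),
    rng: random.Random | None = None,
    number_mask: str = DEFAULT_NUMBER_MASK,
) -> ErrorRecord | None:
    """Plant one error of ``group``'s type in ``target``.

    Tokens are scanned left to right, skipping punctuation, the number
    mask and skip-list words (case-insensitively).  At the first token
    with at least one admissible candidate, one candidate is chosen — at
    random if ``rng`` is given (one rule applied at random within the
    group), else the first in rule order — and the erroneous sentence is
    returned.  ``None`` when no token qualifies.
    """
    skip = {w.lower() for w in skip_list}
    for idx, tok in enumerate(target.tokens):
        if tok in RETAINED_PUNCTUATION or tok == number_mask:
            continue
        low = tok.lower()
        if low in skip:
            continue
        cands = group.admissible(low, lex)
        if not cands:
            continue
        cand = rng.choice(cands) if rng is not None else cands[0]
        error_tok = _restore_case(tok, cand)
        if error_tok == tok:
            continue
        return ErrorRecord(
            source=target.replace_token(idx, error_tok),
            target=target,
            error_type=group.error_type,
            token_index=idx,
            original_token=tok,
            error_token=error_tok,
            distance=indel_distance(low, cand),
        )
    return None
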