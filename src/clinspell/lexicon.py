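"""Corpus-derived lexicon, spelling suggestions and regular-verb analysis.

The lexicon defines "real word" membership: a rule-generated form only
becomes an error if it is attested in the training corpus.  It also backs
a small internal spelling suggester (candidates ranked by indel distance,
then corpus frequency, then alphabetically) and the conjugation-table
lookup used to recognize regular verb forms.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import yaml

from .preprocess import (
    DEFAULT_NUMBER_MASK,
    RETAINED_PUNCTUATION,
    Sentence,
)

CONJUGATION_CLASSES = ("ar", "er", "ir")
TENSES = ("present", "past", "future")
MOODS = ("indicative", "subjunctive")


def _load_packaged_yaml(name: str) -> dict:
    with resources.files("clinspell.data").joinpath(name).open(
        "r", encoding="utf-8"
    ) as fh:
        return yaml.safe_load(fh)


class Lexicon:
    """Word -> occurrence-count map with exact, case-sensitive lookup."""

    def __init__(self, entries: Mapping[str, int] | None = None, min_count: int = 1):
        if min_count < 1:
            raise ValueError("min_count must be >= 1")
        self.min_count = min_count
        self.entries: dict[str, int] = {
            w: c for w, c in (entries or {}).items() if c >= min_count
        }

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Lexicon) and self.entries == other.entries

    def count(self, word: str) -> int:
        return self.entries.get(word, 0)

    def add(self, word: str, count: int = 1) -> None:
        self.entries[word] = self.entries.get(word, 0) + count

    # -- suggestions -----------------------------------------------------

    def suggest(
        self,
        word: str,
        max_distance: int = 3,
        exclusions: Sequence[Callable[[str], bool]] = (),
    ) -> list[str]:
        """Ranked real-word suggestions for ``word``.

        Candidates are lexicon entries within ``max_distance`` indel
        operations of ``word`` (the word itself excluded) that fail every
        exclusion predicate, ordered by distance ascending, corpus
        frequency descending, then lexicographically.
        """
        from .postprocess import indel_distance

        if not word:
            raise ValueError("word must be non-empty")
        scored: list[tuple[int, int, str]] = []
        for cand, cnt in self.entries.items():
            if cand == word or abs(len(cand) - len(word)) > max_distance:
                continue
            d = indel_distance(word, cand)
            if d <= max_distance and not any(excl(cand) for excl in exclusions):
                scored.append((d, -cnt, cand))
        scored.sort()
        return [c for _, _, c in scored]

    # -- serialization ---------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for word in sorted(self.entries):
                fh.write(f"{word}\t{self.entries[word]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, min_count: int = 1) -> "Lexicon":
        entries: dict[str, int] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                try:
                    word, cnt = line.split("\t")
                    entries[word] = int(cnt)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{line_no}: malformed lexicon line {line!r}"
                    ) from exc
        return cls(entries, min_count=min_count)


def build_lexicon(
    sentences: Iterable[Sentence],
    min_count: int = 1,
    number_mask: str = DEFAULT_NUMBER_MASK,
) -> Lexicon:
    """Count every token in the corpus, excluding punctuation and the
    number mask, and keep words occurring at least ``min_count`` times."""
    counts: Counter[str] = Counter()
    for sent in sentences:
        for tok in sent.tokens:
            if tok == number_mask or tok in RETAINED_PUNCTUATION:
                continue
            counts[tok] += 1
    return Lexicon(counts, min_count=min_count)


# ---------------------------------------------------------------------------
# Conjugation tables and verb identification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VerbAnalysis:
    """A regular-verb reading of a word form.

    ``person`` is 1..6 (yo, tú, él/ella, nosotros, vosotros, ellos/ellas).
    For ``haber`` forms, ``termination`` is the whole word and the stem is
    empty.
    """

    infinitive: str
    conjugation_class: str | None
    tense: str
    mood: str
    person: int
    termination: str
    is_haber: bool = False

    @property
    def stem(self) -> str:
        if self.is_haber:
            return ""
        return self.infinitive[: -len(self._class_ending)]

    @property
    def _class_ending(self) -> str:
        return self.conjugation_class or ""


class ConjugationTables:
    """Termination tables for regular -ar/-er/-ir verbs plus ``haber``.

    Only regular paradigms are modeled; "past" is the imperfect.  Within
    one (class, tense, mood) cell some persons share a termination (e.g.
    1st and 3rd singular imperfect), which is inherent to Spanish — person
    swaps must therefore target a *different* termination string.
    """

    def __init__(self, data: dict | None = None):
        data = data or _load_packaged_yaml("conjugations.yaml")
        self.classes: dict[str, dict] = data["classes"]
        self.haber: dict[str, dict[str, list[str]]] = data["haber"]
        self.haber_forms: set[str] = {
            form
            for tense in self.haber.values()
            for row in tense.values()
            for form in row
        }
        # suffix match order: longest first, then canonical table order
        self._ordered: list[tuple[str, str, str, int, str]] = []
        for cls in CONJUGATION_CLASSES:
            terms = self.classes[cls]["terminations"]
            for tense in TENSES:
                for mood in MOODS:
                    for person, term in enumerate(terms[tense][mood], start=1):
                        self._ordered.append((cls, tense, mood, person, term))
        self._ordered.sort(key=lambda t: -len(t[4]))

    def infinitive_ending(self, cls: str) -> str:
        return self.classes[cls]["infinitive_ending"]

    def terminations(self, cls: str, tense: str, mood: str) -> list[str]:
        return self.classes[cls]["terminations"][tense][mood]

    def iter_suffix_entries(self) -> Iterator[tuple[str, str, str, int, str]]:
        """(class, tense, mood, person, termination), longest suffix first."""
        return iter(self._ordered)

    def haber_analysis(self, word: str) -> VerbAnalysis | None:
        for tense in TENSES:
            for mood in MOODS:
                row = self.haber[tense][mood]
                if word in row:
                    return VerbAnalysis(
                        infinitive="haber",
                        conjugation_class=None,
                        tense=tense,
                        mood=mood,
                        person=row.index(word) + 1,
                        termination=word,
                        is_haber=True,
                    )
        return None


def identify_verb(
    word: str, tables: ConjugationTables, lex: Lexicon
) -> VerbAnalysis | None:
    """Recognize ``word`` as a regular conjugated form.

    The longest listed termination whose stem yields an infinitive attested
    in the lexicon wins.  If no termination matches, the whole word is
    compared against the conjugation of ``haber``.  Input is lower-cased
    before matching.
    """
    w = word.lower()
    for cls, tense, mood, person, term in tables.iter_suffix_entries():
        if len(w) > len(term) and w.endswith(term):
            stem = w[: -len(term)]
            infinitive = stem + tables.infinitive_ending(cls)
            if infinitive in lex:
                return VerbAnalysis(
                    infinitive=infinitive,
                    conjugation_class=cls,
                    tense=tense,
                    mood=mood,
                    person=person,
                    termination=term,
                )
    return tables.haber_analysis(w)
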