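"""Synthetic clinical-Spanish corpus, mini-lexicon and reference correctors.

The generator emulates short clinical-report sentences ("El paciente
presenta dolor moderado en la zona .") built from a packaged mini-lexicon
of ~300 clinical-register word forms.  Every inflectional paradigm in the
mini-lexicon is closed under the error rules — each gender, number and
regular-verb form is itself listed — so rule-generated errors on these
words are attested real words and every rule group can fire.

Also provided: oracle / identity correctors (metric sanity anchors), a
deterministic bigram-vote frequency baseline corrector, and adapters for
the line-parallel text dialect consumed by neural-translation toolkits.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from .dataset import DatasetRecord, ParallelDataset, write_parallel
from .errorgen import RuleGroup, _restore_case
from .lexicon import (
    CONJUGATION_CLASSES,
    MOODS,
    TENSES,
    ConjugationTables,
    Lexicon,
)
from .preprocess import RETAINED_PUNCTUATION, Sentence

#: With at least this many sentences, every rule group is observed to fire
#: on the default templates (generous margin; in practice a few dozen
#: sentences suffice).
COVERAGE_N = 1000


def _load_minilex() -> dict:
    with resources.files("clinspell.data").joinpath("minilex.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return yaml.safe_load(fh)


def _four_forms(masc_sg: str) -> tuple[str, str, str, str]:
    """(m sg, f sg, m pl, f pl) for a regular -o/-a paradigm."""
    fem = masc_sg[:-1] + "a"
    return masc_sg, fem, masc_sg + "s", fem + "s"


def conjugate(
    infinitive: str,
    cls: str,
    tense: str,
    mood: str,
    person: int,
    tables: ConjugationTables,
) -> str:
    stem = infinitive[:-2]
    return stem + tables.terminations(cls, tense, mood)[person - 1]


@dataclass
class MiniLexicon:
    """Parsed mini-lexicon with category structure for the templates."""

    nouns: list[tuple[str, str, str]]  # (sg, pl, gender)
    person_nouns: list[str]
    adjectives: list[str]
    verbs: list[tuple[str, str]]  # (infinitive, class)
    homophones: list[str]
    function_words: list[str]
    tables: ConjugationTables

    @classmethod
    def load(cls, tables: ConjugationTables | None = None) -> "MiniLexicon":
        data = _load_minilex()
        return cls(
            nouns=[tuple(n) for n in data["nouns"]],
            person_nouns=list(data["person_nouns"]),
            adjectives=list(data["adjectives"]),
            verbs=[tuple(v) for v in data["verbs"]],
            homophones=list(data["homophones"]),
            function_words=list(data["function_words"]),
            tables=tables or ConjugationTables(),
        )

    def all_forms(self) -> list[str]:
        forms: list[str] = []
        for sg, pl, _ in self.nouns:
            forms += [sg, pl]
        for w in self.person_nouns + self.adjectives:
            forms += list(_four_forms(w))
        for inf, cls in self.verbs:
            forms.append(inf)
            for tense in TENSES:
                for mood in MOODS:
                    for person in range(1, 7):
                        forms.append(
                            conjugate(inf, cls, tense, mood, person, self.tables)
                        )
        forms.append("haber")
        forms += sorted(self.tables.haber_forms)
        forms += self.homophones
        forms += self.function_words
        return forms

    def lexicon(self, corpus: Sequence[Sentence] = ()) -> Lexicon:
        """Lexicon over every mini-lexicon form (base count 1) plus the
        token counts of an optional generated corpus."""
        lex = Lexicon()
        for form in self.all_forms():
            lex.add(form, 1)
        for sent in corpus:
            for tok in sent.tokens:
                if tok not in RETAINED_PUNCTUATION:
                    lex.add(tok.lower(), 1)
        return lex


def mini_lexicon(corpus: Sequence[Sentence] = ()) -> Lexicon:
    """Convenience: the packaged mini-lexicon as a :class:`Lexicon`."""
    return MiniLexicon.load().lexicon(corpus)


# ---------------------------------------------------------------------------
# Sentence templates
# ---------------------------------------------------------------------------

_DET = {("m", "sg"): "el", ("f", "sg"): "la", ("m", "pl"): "los", ("f", "pl"): "las"}
_DET_INDEF = {("m", "sg"): "un", ("f", "sg"): "una", ("m", "pl"): "unos", ("f", "pl"): "unas"}

_PPS = [
    ["en", "la", "zona"],
    ["sin", "molestias"],
    ["tras", "el", "control"],
    ["de", "forma", "prolongada"],
    ["en", "la", "pared"],
    ["por", "la", "herida"],
    ["sin", "señales", "de", "dolor"],
    ["con", "el", "tubo", "de", "drenaje"],
    ["hasta", "el", "control"],
]

_HOMOPHONE_NPS = [
    ["el", "uso", "de", "fármacos"],
    ["el", "hecho", "observado"],
    ["el", "tubo", "de", "drenaje"],
    ["el", "vello", "de", "la", "zona"],
    ["la", "onda", "de", "la", "prueba"],
    ["una", "vasta", "zona"],
]


def _adj_form(masc_sg: str, gender: str, number: str) -> str:
    msg, fsg, mpl, fpl = _four_forms(masc_sg)
    return {("m", "sg"): msg, ("f", "sg"): fsg, ("m", "pl"): mpl, ("f", "pl"): fpl}[
        (gender, number)
    ]


class CorpusGenerator:
    """Template-based sentence sampler over the mini-lexicon."""

    def __init__(self, minilex: MiniLexicon | None = None):
        self.ml = minilex or MiniLexicon.load()
        self.tables = self.ml.tables

    # noun phrase with agreement; returns (tokens, person) for subjects
    def _np(
        self,
        rng: random.Random,
        definite: bool = True,
        with_adj_p: float = 0.6,
    ) -> tuple[list[str], int]:
        if rng.random() < 0.2:
            base = rng.choice(self.ml.person_nouns)
            gender = rng.choice("mf")
            number = rng.choice(["sg", "pl"])
            noun = _adj_form(base, gender, number)
        else:
            sg, pl, gender = rng.choice(self.ml.nouns)
            number = rng.choice(["sg", "pl"])
            noun = sg if number == "sg" else pl
        det = (_DET if definite else _DET_INDEF)[(gender, number)]
        tokens = [det, noun]
        if rng.random() < with_adj_p:
            tokens.append(_adj_form(rng.choice(self.ml.adjectives), gender, number))
        return tokens, 3 if number == "sg" else 6

    def _verb(self, rng: random.Random, person: int) -> str:
        inf, cls = rng.choice(self.ml.verbs)
        tense = rng.choice(TENSES)
        mood = "indicative" if rng.random() < 0.85 else "subjunctive"
        return conjugate(inf, cls, tense, mood, person, self.tables)

    def _sentence_tokens(self, rng: random.Random) -> list[str]:
        kind = rng.randrange(6)
        if kind == 0:
            # subject + verb + object (+ PP)
            subj, person = self._np(rng)
            obj, _ = self._np(rng, definite=rng.random() < 0.5)
            toks = subj + [self._verb(rng, person)] + obj
            if rng.random() < 0.6:
                toks += rng.choice(_PPS)
        elif kind == 1:
            # perfect tense with haber + participle
            subj, person = self._np(rng)
            haber = self.tables.haber["present"]["indicative"][person - 1]
            participle = rng.choice(self.ml.adjectives)
            obj, _ = self._np(rng, definite=False)
            toks = subj + [haber, participle] + obj
        elif kind == 2:
            # impersonal "se" clause
            obj, _ = self._np(rng, definite=rng.random() < 0.5)
            toks = ["se", self._verb(rng, 3)] + obj + rng.choice(_PPS)
        elif kind == 3:
            # homophone-bearing noun phrase as object
            subj, person = self._np(rng, with_adj_p=0.3)
            toks = subj + [self._verb(rng, person)] + rng.choice(_HOMOPHONE_NPS)
        elif kind == 4:
            # copula + agreeing adjective
            subj, person = self._np(rng, with_adj_p=0.0)
            gender = "m" if subj[0] in ("el", "los") else "f"
            number = "sg" if person == 3 else "pl"
            copula = ("está" if person == 3 else "están") if rng.random() < 0.5 else (
                "es" if person == 3 else "son"
            )
            toks = subj + [copula, _adj_form(rng.choice(self.ml.adjectives), gender, number)]
            if rng.random() < 0.5:
                toks += rng.choice(_PPS)
        else:
            # first-person-plural report style
            obj, _ = self._np(rng, definite=False)
            toks = [self._verb(rng, 4)] + obj + rng.choice(_PPS)
        toks[0] = toks[0][0].upper() + toks[0][1:]
        toks.append(".")
        return toks

    def generate(self, n: int, rng: random.Random | int = 0) -> list[Sentence]:
        """``n`` pre-normalized sentences, deterministic under the seed."""
        if isinstance(rng, int):
            rng = random.Random(rng)
        return [
            Sentence(tokens=tuple(self._sentence_tokens(rng)), origin=f"synth:{i}")
            for i in range(n)
        ]


def generate_corpus(
    n: int, rng: random.Random | int = 0, minilex: MiniLexicon | None = None
) -> list[Sentence]:
    """Generate ``n`` synthetic clinical-style sentences."""
    return CorpusGenerator(minilex).generate(n, rng)


# ---------------------------------------------------------------------------
# Reference correctors
# ---------------------------------------------------------------------------


def oracle_corrector(records: Sequence[DatasetRecord]) -> list[Sentence]:
    """Perfect corrector: returns each record's gold sentence."""
    return [r.target for r in records]


def identity_corrector(records: Sequence[DatasetRecord]) -> list[Sentence]:
    """No-op corrector: returns each record's source sentence."""
    return [r.source for r in records]


class FrequencyCorrector:
    """Context bigram-vote baseline corrector.

    For each token, the candidate set is the token itself plus every
    real-word form the six rule groups could reach from it (for a planted
    error this includes the original word, since the rules are largely
    invertible).  Each candidate is scored by the sum of its left and
    right bigram counts in a training corpus; the token is replaced only
    when an alternative strictly beats it (ties keep the source token).
    Deterministic by construction.
    """

    BOS, EOS = "<s>", "</s>"

    def __init__(
        self,
        train_corpus: Sequence[Sentence],
        groups: dict[str, RuleGroup],
        lex: Lexicon,
    ):
        self.groups = groups
        self.lex = lex
        self.bigrams: dict[tuple[str, str], int] = {}
        for sent in train_corpus:
            toks = [self.BOS] + [t.lower() for t in sent.tokens] + [self.EOS]
            for a, b in zip(toks, toks[1:]):
                self.bigrams[(a, b)] = self.bigrams.get((a, b), 0) + 1

    def _score(self, left: str, cand: str, right: str) -> int:
        return self.bigrams.get((left, cand), 0) + self.bigrams.get(
            (cand, right), 0
        )

    def correct_sentence(self, sentence: Sentence) -> Sentence:
        toks = list(sentence.tokens)
        low = [t.lower() for t in toks]
        padded = [self.BOS] + low + [self.EOS]
        for i, tok in enumerate(toks):
            if tok in RETAINED_PUNCTUATION:
                continue
            word = low[i]
            cands = {word}
            for group in self.groups.values():
                cands.update(group.admissible(word, self.lex))
            if len(cands) == 1:
                continue
            left, right = padded[i], padded[i + 2]
            current = self._score(left, word, right)
            best_word, best_score = word, current
            for cand in sorted(cands - {word}):
                s = self._score(left, cand, right)
                if s > best_score:
                    best_word, best_score = cand, s
            if best_word != word:
                toks[i] = _restore_case(tok, best_word)
        return Sentence(tokens=tuple(toks), origin=sentence.origin)

    def __call__(self, records: Sequence[DatasetRecord]) -> list[Sentence]:
        return [self.correct_sentence(r.source) for r in records]


def frequency_corrector(
    records: Sequence[DatasetRecord],
    train_corpus: Sequence[Sentence],
    groups: dict[str, RuleGroup],
    lex: Lexicon,
) -> list[Sentence]:
    """Functional wrapper around :class:`FrequencyCorrector`."""
    return FrequencyCorrector(train_corpus, groups, lex)(records)


# ---------------------------------------------------------------------------
# Neural-translation toolkit adapters (text format only)
# ---------------------------------------------------------------------------


def nmt_adapter_export(
    ds: ParallelDataset, source_path: str | Path, target_path: str | Path
) -> None:
    """Write the dataset as the plain line-parallel source/target files a
    sequence-to-sequence toolkit trains on (no metadata sidecar)."""
    write_parallel(ds, source_path, target_path, meta_path=None)


def nmt_adapter_import(
    predictions_path: str | Path, source_sentences: Sequence[Sentence]
) -> list[list[str]]:
    """Read toolkit predictions (one sentence per line) and validate the
    line count against the source sentences."""
    with open(predictions_path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) != len(source_sentences):
        raise ValueError(
            f"{len(lines)} predictions for {len(source_sentences)} sources"
        )
    return [line.split() for line in lines]
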