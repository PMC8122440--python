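"""Corpus cleaning, sentence splitting and token normalization.

Raw clinical or encyclopedic text is reduced to sentences containing only
words and sentence punctuation: numbers are masked by a constant token,
all other non-alphanumeric symbols become spaces, punctuation is split
into standalone tokens, and letter case is left untouched (a lower-case
sentence start is itself a kind of real-word error we must not destroy).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Pattern, Sequence

#: Punctuation kept as standalone tokens; everything else non-alphanumeric
#: is replaced by a space.
RETAINED_PUNCTUATION = frozenset(".,;:?!")

DEFAULT_NUMBER_MASK = "NUM"
DEFAULT_MIN_TOKENS = 5
DEFAULT_MAX_TOKENS = 40

_DIGIT_RUN = re.compile(r"[0-9]+")
_PUNCT_SPLIT = re.compile(r"([.,;:?!])")
# sentence boundary: terminator, whitespace, then an upper-case letter or digit
_SENT_BOUNDARY = re.compile(r"(?<=[.?!])\s+(?=[A-ZÁÉÍÓÚÜÑ0-9¿¡])")


@dataclass(frozen=True)
class RawSentence:
    """A sentence as cut from the raw text, with provenance."""

    text: str
    origin: str = ""


@dataclass(frozen=True)
class Sentence:
    """A normalized, tokenized sentence."""

    tokens: tuple[str, ...]
    origin: str = field(default="", compare=False)

    @property
    def text(self) -> str:
        return " ".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def replace_token(self, index: int, token: str) -> "Sentence":
        toks = list(self.tokens)
        toks[index] = token
        return Sentence(tokens=tuple(toks), origin=self.origin)


LinePredicate = Callable[[str], bool]


def _as_predicate(p: LinePredicate | str | Pattern[str]) -> LinePredicate:
    if callable(p):
        return p
    pattern = re.compile(p) if isinstance(p, str) else p
    return lambda line: bool(pattern.search(line))


def clean_corpus_lines(
    lines: Iterable[str],
    drop_patterns: Iterable[LinePredicate | str | Pattern[str]] = (),
) -> list[str]:
    """Drop lines matching any predicate (callable, regex string or
    compiled pattern), preserving order.  Used to strip corpus metadata
    such as markup tags and header/footer strings."""
    preds = [_as_predicate(p) for p in drop_patterns]
    return [ln for ln in lines if not any(pred(ln) for pred in preds)]


def split_sentences(text: str, origin: str = "") -> list[RawSentence]:
    """Split decoded text into sentences with a rule-based splitter.

    Newlines always separate sentences; within a line, a terminator
    (``.?!``) followed by whitespace and a capital letter or digit starts a
    new sentence.  Sentence-initial semicolons (an artifact of splitting
    on ``;``-delimited clauses) are stripped.  A pretrained tokenizer can
    be substituted upstream: this function only needs line-shaped input.
    """
    out: list[RawSentence] = []
    for line_no, line in enumerate(text.splitlines()):
        for chunk in _SENT_BOUNDARY.split(line):
            s = chunk.strip()
            while s.startswith(";"):
                s = s[1:].lstrip()
            if s:
                out.append(RawSentence(text=s, origin=f"{origin}:{line_no}"))
    return out


def normalize_sentence(
    raw: RawSentence | str, number_mask: str = DEFAULT_NUMBER_MASK
) -> Sentence:
    """Normalize one sentence into tokens.

    Rules, in order: every maximal digit run becomes the mask token
    (``120/80`` masks each run independently); characters that are neither
    letters nor retained punctuation become spaces; retained punctuation
    is surrounded by spaces so it tokenizes on its own; case is preserved.
    Idempotent on its own output.
    """
    if isinstance(raw, str):
        raw = RawSentence(text=raw)
    text = _DIGIT_RUN.sub(f" {number_mask} ", raw.text)
    text = "".join(
        c if c.isalpha() or c.isspace() or c in RETAINED_PUNCTUATION else " "
        for c in text
    )
    text = _PUNCT_SPLIT.sub(r" \1 ", text)
    return Sentence(tokens=tuple(text.split()), origin=raw.origin)


def length_filter(
    sentences: Sequence[Sentence],
    min_tokens: int = DEFAULT_MIN_TOKENS,
    max_tokens: int = DEFAULT_MAX_TOKENS,
    enabled: bool = True,
) -> list[Sentence]:
    """Keep sentences with ``min_tokens < len <= max_tokens``.

    Very short fragments (link lists, headers) and very long sentences are
    both discarded.  Small corpora are typically not filtered: pass
    ``enabled=False`` to return the input unchanged.
    """
    if min_tokens > max_tokens:
        raise ValueError("min_tokens must be <= max_tokens")
    if not enabled:
        return list(sentences)
    return [s for s in sentences if min_tokens < len(s) <= max_tokens]


def preprocess_text(
    text: str,
    origin: str = "",
    number_mask: str = DEFAULT_NUMBER_MASK,
    min_tokens: int = DEFAULT_MIN_TOKENS,
    max_tokens: int = DEFAULT_MAX_TOKENS,
    filter_length: bool = True,
) -> list[Sentence]:
    """Convenience pipeline: split, normalize, length-filter."""
    sentences = [
        normalize_sentence(raw, number_mask)
        for raw in split_sentences(text, origin)
    ]
    sentences = [s for s in sentences if len(s) > 0]
    return length_filter(sentences, min_tokens, max_tokens, filter_length)
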