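"""Insert/delete-only edit distance and prediction post-processing.

Synthetic real-word errors are produced exclusively by adding and deleting
characters, so the natural distance between an error and its correction is
the Levenshtein distance restricted to insertions and deletions (no
substitutions).  That distance equals ``|a| + |b| - 2 * LCS(a, b)``.

The post-processor reconciles a corrector's raw token stream with the
source sentence: unknown-word placeholders fall back to the source token,
and any predicted token further than a threshold indel distance from its
source token is rejected as an implausible correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .preprocess import Sentence

DEFAULT_UNKNOWN_TOKEN = "<unknown>"
DEFAULT_THRESHOLD = 6


def indel_distance(a: str, b: str) -> int:
    """Minimum number of single-character insertions and deletions
    transforming ``a`` into ``b``.

    Computed as ``len(a) + len(b) - 2 * LCS(a, b)`` with a one-row dynamic
    program.  Characters compare exactly: accented letters are distinct
    from their unaccented counterparts (``'a' != 'á'``).
    """
    if a == b:
        return 0
    # strip common affixes; cheap and effective for inflection pairs
    lo = 0
    hi_a, hi_b = len(a), len(b)
    while lo < hi_a and lo < hi_b and a[lo] == b[lo]:
        lo += 1
    while hi_a > lo and hi_b > lo and a[hi_a - 1] == b[hi_b - 1]:
        hi_a -= 1
        hi_b -= 1
    a, b = a[lo:hi_a], b[lo:hi_b]
    if not a:
        return len(b)
    if not b:
        return len(a)
    # LCS length, rolling row
    prev = [0] * (len(b) + 1)
    for ca in a:
        curr = [0]
        best = 0
        for j, cb in enumerate(b):
            best = prev[j] + 1 if ca == cb else max(prev[j + 1], curr[j])
            curr.append(best)
        prev = curr
    return len(a) + len(b) - 2 * prev[-1]


@dataclass(frozen=True)
class PostprocessConfig:
    """Settings for reconciling predicted tokens with the source sentence.

    ``threshold`` is the maximum indel distance at which a predicted token
    is trusted; errors are generated at distance <= 3 (morphological and
    suggestion types) or <= 6 (verb concordance), hence the default of 6.
    ``strict`` switches the comparison from ``<=`` to ``<``.
    """

    unknown_token: str = DEFAULT_UNKNOWN_TOKEN
    threshold: int = DEFAULT_THRESHOLD
    strict: bool = False

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")

    def accepts(self, source_token: str, predicted_token: str) -> bool:
        d = indel_distance(source_token, predicted_token)
        return d < self.threshold if self.strict else d <= self.threshold


def resolve_prediction(
    source: Sentence,
    predicted: Sequence[str],
    cfg: PostprocessConfig | None = None,
) -> Sentence:
    """Merge a predicted token sequence with its source sentence.

    Position-wise over the source: an unknown-token placeholder or a
    prediction beyond the distance threshold is replaced by the source
    token; positions past the end of the prediction are copied from the
    source (length mismatches are resolved against the source, so the
    output always has the source's length).
    """
    cfg = cfg or PostprocessConfig()
    out: list[str] = []
    for i, src_tok in enumerate(source.tokens):
        if i >= len(predicted):
            out.append(src_tok)
            continue
        pred_tok = predicted[i]
        if pred_tok == cfg.unknown_token:
            out.append(src_tok)
        elif pred_tok == src_tok or cfg.accepts(src_tok, pred_tok):
            out.append(pred_tok)
        else:
            out.append(src_tok)
    return Sentence(tokens=tuple(out), origin=source.origin)
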