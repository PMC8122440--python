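"""Scoring a corrector's output: recall, precision and F0.5.

With ``Total errors`` planted errors, ``Corrected errors`` of them fixed,
and ``Bad corrections`` tokens changed to something that is neither the
source nor the gold token:

    R    = Corrected / Total
    P    = Corrected / (Corrected + Bad)
    F0.5 = 1.25 * P * R / (0.25 * P + R)

F0.5 weighs precision twice as much as recall, the standard trade-off for
correction systems where a false correction is worse than a missed one.
All three are reported as percentages; any 0/0 ratio is defined as 0.

Counting is token-level by default, using the generator's recorded error
position; a strict sentence-level mode (a sentence counts as corrected
only if the whole output equals the gold sentence) is available for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .dataset import DatasetRecord, ParallelDataset
from .preprocess import Sentence


@dataclass
class OutcomeCounts:
    """Raw counts feeding the metric ratios."""

    total_errors: int = 0
    corrected: int = 0
    bad_corrections: int = 0

    def __add__(self, other: "OutcomeCounts") -> "OutcomeCounts":
        return OutcomeCounts(
            self.total_errors + other.total_errors,
            self.corrected + other.corrected,
            self.bad_corrections + other.bad_corrections,
        )


def f05(precision: float, recall: float) -> float:
    """F0.5 from precision and recall (both as percentages)."""
    denom = 0.25 * precision + recall
    if denom == 0:
        return 0.0
    return 1.25 * precision * recall / denom


def compute_metrics(c: OutcomeCounts) -> tuple[float, float, float]:
    """(R, P, F0.5) as percentages, with the 0/0 -> 0 convention."""
    r = 100.0 * c.corrected / c.total_errors if c.total_errors else 0.0
    denom = c.corrected + c.bad_corrections
    p = 100.0 * c.corrected / denom if denom else 0.0
    return r, p, f05(p, r)


def classify_outcomes(
    records: Sequence[DatasetRecord],
    corrected_sentences: Sequence[Sentence],
    sentence_level: bool = False,
) -> tuple[OutcomeCounts, dict[str, OutcomeCounts]]:
    """Count corrected errors and bad corrections, overall and per type.

    Token level (default): an error is corrected iff the output token at
    the recorded error position equals the gold token; every output token
    differing from both the source and the gold token at its position is
    one bad correction (identity records can only contribute bad
    corrections).  Sentence level: corrected iff output == gold sentence;
    bad iff output differs from both gold and source.
    """
    if len(records) != len(corrected_sentences):
        raise ValueError(
            f"{len(records)} records but {len(corrected_sentences)} outputs"
        )
    overall = OutcomeCounts()
    per_type: dict[str, OutcomeCounts] = {}
    for rec_id, (rec, out) in enumerate(zip(records, corrected_sentences)):
        if len(out) != len(rec.source):
            raise ValueError(
                f"record {rec_id}: output has {len(out)} tokens, "
                f"source has {len(rec.source)}"
            )
        counts = OutcomeCounts()
        if sentence_level:
            if not rec.is_identity:
                counts.total_errors = 1
                if out.tokens == rec.target.tokens:
                    counts.corrected = 1
            if out.tokens != rec.target.tokens and out.tokens != rec.source.tokens:
                counts.bad_corrections = 1
        else:
            if not rec.is_identity:
                counts.total_errors = 1
                if out.tokens[rec.token_index] == rec.target.tokens[rec.token_index]:
                    counts.corrected = 1
            for o, s, t in zip(out.tokens, rec.source.tokens, rec.target.tokens):
                if o != s and o != t:
                    counts.bad_corrections += 1
        overall += counts
        if not rec.is_identity:
            per_type[rec.error_type] = (
                per_type.get(rec.error_type, OutcomeCounts()) + counts
            )
    return overall, per_type


@dataclass
class EvalReport:
    """Per-error-type and overall counts and metrics."""

    overall: OutcomeCounts
    per_type: dict[str, OutcomeCounts] = field(default_factory=dict)
    sentence_level: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Rows per error type plus 'overall'; columns: counts and R/P/F0.5
        rounded to two decimals."""
        rows = []
        for name, counts in [*sorted(self.per_type.items()), ("overall", self.overall)]:
            r, p, f = compute_metrics(counts)
            rows.append(
                {
                    "error_type": name,
                    "total": counts.total_errors,
                    "corrected": counts.corrected,
                    "bad": counts.bad_corrections,
                    "R": round(r, 2),
                    "P": round(p, 2),
                    "F0.5": round(f, 2),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self) -> dict:
        out = {}
        for name, counts in [*self.per_type.items(), ("overall", self.overall)]:
            r, p, f = compute_metrics(counts)
            out[name] = {
                "total": counts.total_errors,
                "corrected": counts.corrected,
                "bad": counts.bad_corrections,
                "R": round(r, 2),
                "P": round(p, 2),
                "F0.5": round(f, 2),
            }
        return out


def report(
    ds: ParallelDataset | Sequence[DatasetRecord],
    corrected_sentences: Sequence[Sentence],
    sentence_level: bool = False,
) -> EvalReport:
    """Score corrected sentences against a dataset's records."""
    records = list(ds)
    overall, per_type = classify_outcomes(
        records, corrected_sentences, sentence_level=sentence_level
    )
    return EvalReport(overall=overall, per_type=per_type, sentence_level=sentence_level)
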