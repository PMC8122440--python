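"""Parallel-dataset compilation, splitting and line-aligned text I/O.

Two compilation strategies turn a clean corpus into (source, target)
sentence pairs for training an error corrector:

* strategy 1 — for every correct sentence, each of the six rule groups is
  attempted once (one randomly chosen applicable rule per group), giving
  up to six single-error sentences, and the correct sentence is always
  appended as an identity pair (data augmentation);
* strategy 2 — exactly one output per correct sentence: the groups are
  tried in a random order and the first that fires wins, with the
  identity pair emitted only when no group can generate an error.

On disk, a dataset is a pair of line-aligned text files (the dialect
consumed by neural-translation toolkits) plus a JSONL metadata sidecar.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errorgen import ERROR_TYPES, ErrorRecord, RuleGroup, generate_error
from .lexicon import Lexicon
from .preprocess import Sentence

IDENTITY = "identity"

TRAIN, VALIDATION, TEST = "train", "validation", "test"


@dataclass(frozen=True)
class DatasetRecord:
    """One (source, target) pair with error metadata and a split label."""

    source: Sentence
    target: Sentence
    error_type: str = IDENTITY
    token_index: int | None = None
    original_token: str | None = None
    error_token: str | None = None
    distance: int | None = None
    split: str | None = None

    @classmethod
    def from_error(cls, rec: ErrorRecord) -> "DatasetRecord":
        return cls(
            source=rec.source,
            target=rec.target,
            error_type=rec.error_type,
            token_index=rec.token_index,
            original_token=rec.original_token,
            error_token=rec.error_token,
            distance=rec.distance,
        )

    @classmethod
    def identity(cls, sentence: Sentence) -> "DatasetRecord":
        return cls(source=sentence, target=sentence)

    @property
    def is_identity(self) -> bool:
        return self.error_type == IDENTITY

    def validate(self) -> None:
        if len(self.source) != len(self.target):
            raise ValueError("source/target token counts differ")
        if self.is_identity:
            if self.source != self.target:
                raise ValueError("identity record with source != target")
            return
        diffs = [
            i
            for i, (s, t) in enumerate(zip(self.source.tokens, self.target.tokens))
            if s != t
        ]
        if diffs != [self.token_index]:
            raise ValueError(
                f"record differs at {diffs}, metadata says {self.token_index}"
            )
        if self.source.tokens[self.token_index] != self.error_token:
            raise ValueError("error_token inconsistent with source sentence")
        if self.target.tokens[self.token_index] != self.original_token:
            raise ValueError("original_token inconsistent with target sentence")


class ParallelDataset:
    """Ordered collection of :class:`DatasetRecord`."""

    def __init__(self, records: Iterable[DatasetRecord] = ()):
        self.records: list[DatasetRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DatasetRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ParallelDataset) and self.records == other.records
        )

    def subset(self, split: str) -> "ParallelDataset":
        return ParallelDataset(r for r in self.records if r.split == split)

    def error_records(self) -> list[DatasetRecord]:
        return [r for r in self.records if not r.is_identity]

    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.error_type] = counts.get(r.error_type, 0) + 1
        return counts


def compile_strategy1(
    corpus: Sequence[Sentence],
    groups: dict[str, RuleGroup],
    lex: Lexicon,
    skip_list: Iterable[str] = (),
    rng: random.Random | None = None,
) -> ParallelDataset:
    """Many erroneous sentences per correct sentence (one per group that
    fires), each followed by the identity pair."""
    rng = rng or random.Random(0)
    skip = frozenset(w.lower() for w in skip_list)
    records: list[DatasetRecord] = []
    for sent in corpus:
        for etype in ERROR_TYPES:
            rec = generate_error(sent, groups[etype], lex, skip, rng)
            if rec is not None:
                records.append(DatasetRecord.from_error(rec))
        records.append(DatasetRecord.identity(sent))
    return ParallelDataset(records)


def compile_strategy2(
    corpus: Sequence[Sentence],
    groups: dict[str, RuleGroup],
    lex: Lexicon,
    skip_list: Iterable[str] = (),
    rng: random.Random | None = None,
) -> ParallelDataset:
    """Exactly one output per correct sentence: groups are tried in a
    uniformly shuffled order and the first success wins; the identity pair
    is the fallback when no group fires."""
    rng = rng or random.Random(0)
    skip = frozenset(w.lower() for w in skip_list)
    records: list[DatasetRecord] = []
    for sent in corpus:
        order = list(ERROR_TYPES)
        rng.shuffle(order)
        rec = None
        for etype in order:
            rec = generate_error(sent, groups[etype], lex, skip, rng)
            if rec is not None:
                break
        records.append(
            DatasetRecord.from_error(rec)
            if rec is not None
            else DatasetRecord.identity(sent)
        )
    return ParallelDataset(records)


def split_dataset(
    ds: ParallelDataset,
    n_validation: int,
    n_test: int,
    rng: random.Random | None = None,
    include_identity_in_test: bool = False,
) -> ParallelDataset:
    """Assign train/validation/test labels by sampling without replacement.

    The test split is stratified by error type: each type contributes
    ``n_test // n_types`` records, truncated to the smallest per-type
    count when exact balance is infeasible.  Identity records are kept out
    of the test split by default.  Remaining records are sampled for
    validation; everything else is training data.
    """
    rng = rng or random.Random(0)
    if n_validation < 0 or n_test < 0:
        raise ValueError("split sizes must be >= 0")
    if n_validation + n_test > len(ds):
        raise ValueError(
            f"requested validation={n_validation} + test={n_test} records "
            f"but dataset has only {len(ds)}"
        )
    by_type: dict[str, list[int]] = {}
    for i, rec in enumerate(ds.records):
        if rec.is_identity and not include_identity_in_test:
            continue
        by_type.setdefault(rec.error_type, []).append(i)

    test_idx: set[int] = set()
    if n_test > 0 and by_type:
        per_type = n_test // len(by_type)
        per_type = min(per_type, min(len(v) for v in by_type.values()))
        for idxs in by_type.values():
            test_idx.update(rng.sample(idxs, per_type))

    remaining = [i for i in range(len(ds)) if i not in test_idx]
    val_idx = set(rng.sample(remaining, n_validation))

    labelled = []
    for i, rec in enumerate(ds.records):
        split = TEST if i in test_idx else VALIDATION if i in val_idx else TRAIN
        labelled.append(replace(rec, split=split))
    return ParallelDataset(labelled)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_parallel(
    ds: ParallelDataset,
    source_path: str | Path,
    target_path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    """Write line-aligned source/target files and optional JSONL metadata."""
    with open(source_path, "w", encoding="utf-8") as src, open(
        target_path, "w", encoding="utf-8"
    ) as tgt:
        for rec in ds.records:
            src.write(rec.source.text + "\n")
            tgt.write(rec.target.text + "\n")
    if meta_path is not None:
        with open(meta_path, "w", encoding="utf-8") as meta:
            for i, rec in enumerate(ds.records):
                meta.write(
                    json.dumps(
                        {
                            "id": i,
                            "split": rec.split,
                            "error_type": rec.error_type,
                            "token_index": rec.token_index,
                            "original": rec.original_token,
                            "error": rec.error_token,
                            "distance": rec.distance,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )


def read_parallel(
    source_path: str | Path,
    target_path: str | Path,
    meta_path: str | Path | None = None,
) -> ParallelDataset:
    """Read a dataset back; inverse of :func:`write_parallel`.

    Raises on misaligned files, reporting the offending line number.
    """
    with open(source_path, encoding="utf-8") as fh:
        src_lines = fh.read().splitlines()
    with open(target_path, encoding="utf-8") as fh:
        tgt_lines = fh.read().splitlines()
    if len(src_lines) != len(tgt_lines):
        raise ValueError(
            f"line count mismatch: {len(src_lines)} source vs "
            f"{len(tgt_lines)} target (first divergence at line "
            f"{min(len(src_lines), len(tgt_lines)) + 1})"
        )
    metas: list[dict] = []
    if meta_path is not None:
        with open(meta_path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, 1):
                if line.strip():
                    try:
                        metas.append(json.loads(line))
                    except json.JSONDecodeError as exc:
                        raise ValueError(
                            f"{meta_path}:{line_no}: malformed metadata"
                        ) from exc
        if len(metas) != len(src_lines):
            raise ValueError(
                f"metadata has {len(metas)} records for {len(src_lines)} lines"
            )
    records = []
    for i, (s, t) in enumerate(zip(src_lines, tgt_lines)):
        source = Sentence(tokens=tuple(s.split()))
        target = Sentence(tokens=tuple(t.split()))
        if metas:
            m = metas[i]
            records.append(
                DatasetRecord(
                    source=source,
                    target=target,
                    error_type=m["error_type"],
                    token_index=m["token_index"],
                    original_token=m["original"],
                    error_token=m["error"],
                    distance=m["distance"],
                    split=m["split"],
                )
            )
        else:
            etype = IDENTITY if s == t else "unknown"
            records.append(
                DatasetRecord(source=source, target=target, error_type=etype)
            )
    return ParallelDataset(records)
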