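"""Homopolymer and alternating-dipeptide repeat detection.

Scans protein sequences for polyglutamine (polyQ), polyalanine (polyA)
and strictly alternating glutamine–alanine (polyQA) runs, and classifies
proteins into the Q4/A4/QA4 groups (at least one run of ``min_len``
residues, default 4, of the corresponding kind).

Conventions
-----------
* Coordinates are 0-based, half-open ``[start, end)``.
* Runs are maximal: they cannot be extended on either side.
* Ambiguity letters (X, U, B, Z) never match Q or A and break runs.
* A residue may belong simultaneously to a homopolymer run and to a QA
  alternating run; the Q4/A4/QA4 flags are independent classifications.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import ProteinRecord, SequenceError, VALID_AA

#: shared default threshold for Q4/A4/QA4 calling and overlap counting
DEFAULT_MIN_LEN = 4


@dataclass(frozen=True)
class RepeatRun:
    """A maximal repeat run with half-open coordinates."""

    protein_id: str
    kind: str  # "Q", "A" or "QA"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatFlags:
    protein_id: str
    has_Q4: bool
    has_A4: bool
    has_QA4: bool


def _check_letters(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in VALID_AA:
            raise SequenceError(
                f"invalid character {ch!r} at position {i} in sequence"
            )


def scan_homopolymer(
    seq: str,
    residue: str,
    min_len: int = DEFAULT_MIN_LEN,
    protein_id: str = "",
) -> list[RepeatRun]:
    """All maximal runs of ``residue`` with length >= ``min_len``.

    Returns runs sorted by start; maximal runs of a single letter can
    neither overlap nor abut. An empty sequence yields an empty list.
    """
    if len(residue) != 1 or residue not in VALID_AA - set("XUBZ"):
        raise ValueError(f"residue must be one standard amino-acid letter, got {residue!r}")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    _check_letters(seq)

    runs: list[RepeatRun] = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == residue:
            j = i
            while j < n and seq[j] == residue:
                j += 1
            if j - i >= min_len:
                runs.append(RepeatRun(protein_id, residue, i, j))
            i = j
        else:
            i += 1
    return runs


def scan_qa_alternation(
    seq: str,
    min_len: int = DEFAULT_MIN_LEN,
    protein_id: str = "",
) -> list[RepeatRun]:
    """All maximal strictly alternating Q/A runs containing both letters.

    Either phase (``QAQA...`` or ``AQAQ...``) qualifies. Two maximal
    alternating runs may share a boundary letter-count but never
    overlap: a doubled letter (``...QQ...``) ends one run at the first Q
    and starts the next at the second.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2 for alternating runs")
    _check_letters(seq)

    runs: list[RepeatRun] = []
    start: int | None = None

    def close(end: int) -> None:
        nonlocal start
        if start is not None:
            sub = seq[start:end]
            if end - start >= min_len and "Q" in sub and "A" in sub:
                runs.append(RepeatRun(protein_id, "QA", start, end))
        start = None

    for i, ch in enumerate(seq):
        if ch not in ("Q", "A"):
            close(i)
        elif start is None:
            start = i
        elif ch == seq[i - 1]:
            close(i)
            start = i
    close(len(seq))
    return runs


def scan_all(
    record: ProteinRecord, min_len: int = DEFAULT_MIN_LEN
) -> list[RepeatRun]:
    """All Q, A and QA runs of a protein, sorted by (kind, start)."""
    runs = scan_homopolymer(record.seq, "Q", min_len, record.id)
    runs += scan_homopolymer(record.seq, "A", min_len, record.id)
    runs += scan_qa_alternation(record.seq, min_len, record.id)
    return runs


def classify_protein(
    record: ProteinRecord, min_len: int = DEFAULT_MIN_LEN
) -> RepeatFlags:
    """Q4/A4/QA4 membership flags for one protein."""
    return RepeatFlags(
        protein_id=record.id,
        has_Q4=bool(scan_homopolymer(record.seq, "Q", min_len, record.id)),
        has_A4=bool(scan_homopolymer(record.seq, "A", min_len, record.id)),
        has_QA4=bool(scan_qa_alternation(record.seq, min_len, record.id)),
    )


def repeat_mask(runs: Iterable[RepeatRun], seq_len: int) -> set[int]:
    """Union of the runs' residue index sets; idempotent under duplicates."""
    mask: set[int] = set()
    for run in runs:
        if run.start < 0 or run.end > seq_len:
            raise ValueError(
                f"run [{run.start},{run.end}) out of bounds for length {seq_len}"
            )
        mask.update(range(run.start, run.end))
    return mask


# ---------------------------------------------------------------- tables

RUN_COLUMNS = ["protein_id", "kind", "start0", "end0", "length"]
FLAG_COLUMNS = ["protein_id", "has_Q4", "has_A4", "has_QA4"]


def runs_to_frame(runs: Sequence[RepeatRun]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.protein_id, r.kind, r.start, r.end, r.length) for r in runs],
        columns=RUN_COLUMNS,
    )


def flags_to_frame(flags: Sequence[RepeatFlags]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.protein_id, f.has_Q4, f.has_A4, f.has_QA4) for f in flags],
        columns=FLAG_COLUMNS,
    )


def write_runs(runs: Sequence[RepeatRun], path: str | Path) -> None:
    runs_to_frame(runs).to_csv(path, sep="\t", index=False)


def read_runs(path: str | Path) -> list[RepeatRun]:
    df = pd.read_csv(path, sep="\t")
    return [
        RepeatRun(row.protein_id, row.kind, int(row.start0), int(row.end0))
        for row in df.itertuples()
    ]


def write_flags(flags: Sequence[RepeatFlags], path: str | Path) -> None:
    flags_to_frame(flags).to_csv(path, sep="\t", index=False)


def read_flags(path: str | Path) -> list[RepeatFlags]:
    df = pd.read_csv(path, sep="\t")
    return [
        RepeatFlags(row.protein_id, bool(row.has_Q4), bool(row.has_A4), bool(row.has_QA4))
        for row in df.itertuples()
    ]
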