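"""Coiled-coil propensity tracks and segment calling.

A coiled-coil (CC) predictor such as Paircoil2 emits a per-residue
P-score in [0, 1]; lower means stronger CC prediction, and CC propensity
is defined as ``1 - P``. This module ingests such tracks (the external
predictor is consumed, never called), calls CC segments as maximal runs
of residues with ``P`` strictly below a threshold (default 0.05), and
offers a naive hydrophobic-periodicity scorer so the downstream pipeline
can be exercised without any external predictor. The naive scorer is
deliberately simple plumbing, not a reimplementation of any published
predictor.

Proteins shorter than the external predictor's minimum length carry
all-missing tracks and count as non-CC proteins; a protein is a "CC
protein" iff it has at least one called segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: detection threshold on the P-score (strict inequality)
DEFAULT_P_THRESHOLD = 0.05

#: residues counted as core-compatible by the naive heptad scorer
NAIVE_HYDROPHOBIC = set("LIVMFAQ")


class TrackError(ValueError):
    """Raised for malformed CC track tables."""


@dataclass(frozen=True)
class CCTrack:
    """Per-residue P-scores aligned to one protein sequence.

    ``p_scores`` has one float per residue; NaN marks residues the
    predictor did not score.
    """

    protein_id: str
    p_scores: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p_scores, dtype=float)
        object.__setattr__(self, "p_scores", p)
        finite = p[~np.isnan(p)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise TrackError("P-scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.p_scores)


@dataclass(frozen=True)
class CCSegment:
    """A maximal run of residues with P-score below the calling threshold."""

    protein_id: str
    start: int
    end: int
    min_p: float

    @property
    def length(self) -> int:
        return self.end - self.start


def parse_cc_track(
    table: str,
    protein_id: str,
    seq_len: int,
    seq: str | None = None,
) -> CCTrack:
    """Parse a Paircoil2-style per-residue table into a :class:`CCTrack`.

    Rows are tab- or whitespace-separated ``(position_1based, residue,
    p_score)``; ``#``-prefixed comment lines and blank lines are
    ignored. Unlisted positions are marked missing. Errors carry the
    offending 1-based row number of the source text.
    """
    p = np.full(seq_len, np.nan)
    seen: set[int] = set()
    for row_no, raw in enumerate(table.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise TrackError(f"row {row_no}: expected (position, residue, p_score)")
        try:
            pos = int(fields[0])
            score = float(fields[2])
        except ValueError as exc:
            raise TrackError(f"row {row_no}: {exc}") from None
        if not 1 <= pos <= seq_len:
            raise TrackError(
                f"row {row_no}: position {pos} outside 1..{seq_len}"
            )
        if pos in seen:
            raise TrackError(f"row {row_no}: duplicate position {pos}")
        if not 0.0 <= score <= 1.0:
            raise TrackError(f"row {row_no}: P-score {score} outside [0, 1]")
        if seq is not None and fields[1] != seq[pos - 1]:
            raise TrackError(
                f"row {row_no}: residue {fields[1]!r} does not match "
                f"sequence letter {seq[pos - 1]!r} at position {pos}"
            )
        seen.add(pos)
        p[pos - 1] = score
    return CCTrack(protein_id, p)


def write_track(track: CCTrack, seq: str | None = None) -> str:
    """Serialize a track to the same dialect :func:`parse_cc_track` reads."""
    lines = [f"# protein_id={track.protein_id}", "# position\tresidue\tp_score"]
    for i, score in enumerate(track.p_scores):
        if math.isnan(score):
            continue
        letter = seq[i] if seq is not None else "-"
        lines.append(f"{i + 1}\t{letter}\t{score:.6g}")
    return "\n".join(lines) + "\n"


def propensity(track: CCTrack) -> np.ndarray:
    """CC propensity, 1 - P; missing scores stay missing (NaN)."""
    return 1.0 - track.p_scores


def call_cc_segments(
    track: CCTrack,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_seg_len: int = 1,
) -> list[CCSegment]:
    """Maximal runs of residues with ``P < p_threshold`` (strict).

    Missing values break segments. Returned segments are sorted and
    non-overlapping and together cover exactly the set
    ``{i : P_i < p_threshold}`` (when ``min_seg_len`` is 1).
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    p = track.p_scores
    below = ~np.isnan(p) & (p < p_threshold)
    segments: list[CCSegment] = []
    i, n = 0, len(p)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_seg_len:
                segments.append(
                    CCSegment(track.protein_id, i, j, float(np.min(p[i:j])))
                )
            i = j
        else:
            i += 1
    return segments


def cc_mask(segments: Iterable[CCSegment], seq_len: int) -> set[int]:
    """Union of segment residue indices (same semantics as repeat_mask)."""
    mask: set[int] = set()
    for seg in segments:
        if seg.start < 0 or seg.end > seq_len:
            raise ValueError(
                f"segment [{seg.start},{seg.end}) out of bounds for length {seq_len}"
            )
        mask.update(range(seg.start, seg.end))
    return mask


def naive_heptad_score(seq: str, window: int = 21) -> np.ndarray:
    """Pseudo-P-scores from windowed hydrophobic heptad periodicity.

    For each residue with a full centered window, every heptad frame is
    tried and the fraction of a/d core positions occupied by
    hydrophobic/core-compatible letters (L, I, V, M, F, A, Q) is
    computed; the pseudo-P is one minus the best fraction, so perfect
    heptad periodicity scores 0 and an apolar-free window scores 1.
    Residues without a full window (or every residue, when the sequence
    is shorter than the window) are NaN. Deterministic; intended only as
    self-contained plumbing for pipeline tests.
    """
    if window < 7 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 7")
    n = len(seq)
    out = np.full(n, np.nan)
    if n < window:
        return out
    half = window // 2
    hydro = np.array([ch in NAIVE_HYDROPHOBIC for ch in seq])
    offsets = np.arange(-half, half + 1)
    for i in range(half, n - half):
        win = hydro[i - half : i + half + 1]
        best = 0.0
        for frame in range(7):
            core = ((offsets + frame) % 7 == 0) | ((offsets + frame) % 7 == 3)
            frac = win[core].mean()
            best = max(best, float(frac))
        out[i] = 1.0 - best
    return out


def naive_track(protein_id: str, seq: str, window: int = 21) -> CCTrack:
    return CCTrack(protein_id, naive_heptad_score(seq, window))


# ---------------------------------------------------------------- tables

SEGMENT_COLUMNS = ["protein_id", "start0", "end0", "min_p"]


def segments_to_frame(segments: Sequence[CCSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.protein_id, s.start, s.end, s.min_p) for s in segments],
        columns=SEGMENT_COLUMNS,
    )


def write_segments(segments: Sequence[CCSegment], path: str | Path) -> None:
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> list[CCSegment]:
    df = pd.read_csv(path, sep="\t")
    return [
        CCSegment(row.protein_id, int(row.start0), int(row.end0), float(row.min_p))
        for row in df.itertuples()
    ]
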