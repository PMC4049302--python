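"""Proteome-level repeat/coiled-coil statistics.

Implements the screening statistics: per-proteome occurrence percentages
of Q4/A4/QA4 and CC proteins, co-occurrence enrichment under an
independence null (Yates-corrected chi-squared, Fisher's exact as an
alternative for tiny counts), the relative-length expected-overlap null
for CC/repeat overlap within proteins, the observed-vs-expected >=4
residue overlap dichotomy test, the %A4/%Q4 ratio, the normalized
co-occurrence metric %(Q4&A4)/(%A4)^2, and Pearson correlations of these
metrics with species divergence times.

Percentages are kept on the 0-100 scale throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .repeats import RepeatFlags

#: minimum residue overlap for the observed/expected dichotomy
DEFAULT_OVERLAP_THRESHOLD = 4

CLASSES = ("Q4", "A4", "QA4", "CC")
INTERSECTIONS = (
    ("Q4", "A4"),
    ("Q4", "QA4"),
    ("A4", "QA4"),
    ("Q4", "A4", "QA4"),
    ("CC", "Q4"),
    ("CC", "A4"),
    ("CC", "QA4"),
)


def _key(classes: Sequence[str]) -> str:
    return "&".join(classes)


@dataclass(frozen=True)
class ProteomeSummary:
    """Counts and percentages of repeat/CC classes in one proteome."""

    species: str
    n_proteins: int
    counts: Mapping[str, int]

    def count(self, *classes: str) -> int:
        return self.counts[_key(classes)]

    def percent(self, *classes: str) -> float:
        return 100.0 * self.count(*classes) / self.n_proteins

    def venn_counts(self) -> dict[str, int]:
        """Venn-ready counts over the three repeat classes."""
        keys = ["Q4", "A4", "QA4", "Q4&A4", "Q4&QA4", "A4&QA4", "Q4&A4&QA4"]
        return {k: self.counts[k] for k in keys}

    def to_dict(self) -> dict:
        out: dict = {"species": self.species, "n_proteins": self.n_proteins}
        for key, cnt in self.counts.items():
            out[f"n_{key}"] = cnt
            out[f"pct_{key}"] = 100.0 * cnt / self.n_proteins
        return out


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs expected counts under a stated null."""

    observed: int
    expected: float
    ratio: float  # NaN when flagged undefined
    chi2: float
    p_value: float
    method: str = "chi2_yates"
    note: str = ""

    @property
    def undefined(self) -> bool:
        return bool(self.note)

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "expected": self.expected,
            "ratio": self.ratio,
            "chi2": self.chi2,
            "p_value": self.p_value,
            "method": self.method,
            "note": self.note,
        }


@dataclass(frozen=True)
class OverlapRecord:
    """Per-protein CC/repeat overlap bookkeeping."""

    protein_id: str
    protein_len: int
    cc_len: int
    rep_len: int
    observed_overlap: int
    expected_overlap: float


@dataclass(frozen=True)
class PhyloPoint:
    species: str
    divergence_mya: float
    value: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n_points: int
    note: str = ""


# ------------------------------------------------------------- summaries


def summarize_proteome(
    flags: Sequence[RepeatFlags],
    cc_flags: Mapping[str, bool] | None = None,
    species: str = "",
) -> ProteomeSummary:
    """Exact counts and percentages for all classes and intersections.

    ``cc_flags`` maps protein_id to "has at least one called CC
    segment"; when omitted, CC membership is False everywhere and the
    CC-involving statistics are vacuous.
    """
    if not flags:
        raise ValueError("empty proteome: no repeat flags supplied")
    ids = [f.protein_id for f in flags]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in flags")
    if cc_flags is not None:
        missing = sorted(set(ids) - set(cc_flags))
        extra = sorted(set(cc_flags) - set(ids))
        if missing or extra:
            raise ValueError(
                f"flags/cc_flags key mismatch; missing from cc_flags: {missing[:5]}, "
                f"unknown ids in cc_flags: {extra[:5]}"
            )

    member = {
        "Q4": {f.protein_id for f in flags if f.has_Q4},
        "A4": {f.protein_id for f in flags if f.has_A4},
        "QA4": {f.protein_id for f in flags if f.has_QA4},
        "CC": {pid for pid in ids if cc_flags and cc_flags[pid]},
    }
    counts: dict[str, int] = {c: len(member[c]) for c in CLASSES}
    for combo in INTERSECTIONS:
        counts[_key(combo)] = len(set.intersection(*(member[c] for c in combo)))
    return ProteomeSummary(species=species, n_proteins=len(flags), counts=counts)


# ---------------------------------------------------------- co-occurrence


def cooccurrence_test(
    n_A: int, n_B: int, n_AB: int, N: int, method: str = "chi2_yates"
) -> EnrichmentResult:
    """Enrichment of joint membership against the independence null.

    Expected joint count is ``N * (n_A/N) * (n_B/N)``. The test is a
    Yates-corrected chi-squared on the 2x2 contingency table with the
    given margins (``method="fisher"`` substitutes Fisher's exact test,
    useful for tiny fixtures). Zero margins yield a flagged result with
    undefined ratio.
    """
    if not (0 <= n_AB <= min(n_A, n_B) <= max(n_A, n_B) <= N):
        raise ValueError(
            f"inconsistent counts: n_A={n_A}, n_B={n_B}, n_AB={n_AB}, N={N}"
        )
    if n_A == 0 or n_B == 0:
        return EnrichmentResult(
            observed=n_AB, expected=0.0, ratio=math.nan, chi2=math.nan,
            p_value=math.nan, method=method, note="zero margin: ratio undefined",
        )
    expected = n_A * n_B / N
    ratio = n_AB / expected
    table = np.array(
        [[n_AB, n_A - n_AB], [n_B - n_AB, N - n_A - n_B + n_AB]]
    )
    if method == "fisher":
        _, p = stats.fisher_exact(table)
        chi2 = math.nan
    elif method == "chi2_yates":
        if table.min() == 0 and (table.sum(0).min() == 0 or table.sum(1).min() == 0):
            # degenerate margins cannot occur here (n_A, n_B > 0, N >= n_A + n_B)
            raise AssertionError("unreachable degenerate table")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        chi2, p = float(chi2), float(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return EnrichmentResult(
        observed=n_AB, expected=expected, ratio=ratio, chi2=chi2,
        p_value=float(p), method=method,
    )


def cc_association_test(
    summary: ProteomeSummary, repeat_class: str, method: str = "chi2_yates"
) -> EnrichmentResult:
    """Association of one repeat class with CC proteins (obs vs exp)."""
    if repeat_class not in ("Q4", "A4", "QA4"):
        raise ValueError(f"repeat_class must be Q4, A4 or QA4, got {repeat_class!r}")
    return cooccurrence_test(
        n_A=summary.count(repeat_class),
        n_B=summary.count("CC"),
        n_AB=summary.count("CC", repeat_class),
        N=summary.n_proteins,
        method=method,
    )


# ------------------------------------------------------ overlap null model


def expected_overlap(L: int, cc_len: int, rep_len: int) -> float:
    """Chance CC/repeat overlap from relative lengths: cc_len*rep_len/L."""
    if L < 1:
        raise ValueError("protein length must be >= 1")
    if not (0 <= cc_len <= L and 0 <= rep_len <= L):
        raise ValueError("segment total lengths must lie in [0, L]")
    return cc_len * rep_len / L


def permutation_oracle(
    L: int,
    cc_seg_lengths: Sequence[int],
    rep_seg_lengths: Sequence[int],
    n_iter: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo mean and standard error of chance overlap.

    Each iteration re-places both segment sets uniformly at random at
    non-overlapping integer positions within ``[0, L)`` and measures the
    total residue overlap between the two sets. Validates the
    closed-form expectation of :func:`expected_overlap` for segments
    short relative to ``L`` and quantifies its edge-effect bias
    otherwise. Deterministic given ``seed``.
    """
    cc = np.asarray(cc_seg_lengths, dtype=int)
    rep = np.asarray(rep_seg_lengths, dtype=int)
    for lens, label in ((cc, "cc"), (rep, "repeat")):
        if lens.size and lens.min() < 1:
            raise ValueError(f"{label} segment lengths must be >= 1")
        if lens.sum() > L:
            raise ValueError(f"{label} segments do not fit in length {L}")
    if cc.size == 0 or rep.size == 0:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)

    def place(lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # random order, then uniform non-overlapping packing via sorted slack
        k = lengths.size
        order = np.argsort(rng.random((n_iter, k)), axis=1)
        lens = lengths[order]
        free = L - int(lengths.sum())
        slack = np.sort(rng.integers(0, free + 1, size=(n_iter, k)), axis=1)
        starts = slack + np.concatenate(
            [np.zeros((n_iter, 1), dtype=int), np.cumsum(lens, axis=1)[:, :-1]],
            axis=1,
        )
        return starts, lens

    s1, l1 = place(cc)
    s2, l2 = place(rep)
    e1, e2 = s1 + l1, s2 + l2
    lo = np.maximum(s1[:, :, None], s2[:, None, :])
    hi = np.minimum(e1[:, :, None], e2[:, None, :])
    overlap = np.clip(hi - lo, 0, None).sum(axis=(1, 2))
    mean = float(overlap.mean())
    se = float(overlap.std(ddof=1) / math.sqrt(n_iter)) if n_iter > 1 else 0.0
    return mean, se


def build_overlap_records(
    protein_lengths: Mapping[str, int],
    repeat_masks: Mapping[str, set[int]],
    cc_masks: Mapping[str, set[int]],
) -> list[OverlapRecord]:
    """Per-protein overlap bookkeeping from residue masks.

    ``repeat_masks``/``cc_masks`` map protein_id to the union residue
    index set of its repeat runs / called CC segments (absent id =
    empty mask).
    """
    records = []
    for pid, L in protein_lengths.items():
        rep = repeat_masks.get(pid, set())
        cc = cc_masks.get(pid, set())
        records.append(
            OverlapRecord(
                protein_id=pid,
                protein_len=L,
                cc_len=len(cc),
                rep_len=len(rep),
                observed_overlap=len(cc & rep),
                expected_overlap=expected_overlap(L, len(cc), len(rep)),
            )
        )
    return records


def overlap_class_test(
    records: Sequence[OverlapRecord],
    overlap_threshold: int = DEFAULT_OVERLAP_THRESHOLD,
    include_all: bool = False,
) -> EnrichmentResult:
    """Observed vs expected counts of proteins with overlap >= threshold.

    Restricted (by default) to proteins possessing both a CC segment and
    a repeat run. ``observed`` counts proteins whose measured overlap
    reaches the threshold; ``expected`` counts proteins whose
    relative-length expected overlap reaches it. The comparison is a
    Yates-corrected goodness-of-fit chi-squared on the >=/< dichotomy.
    """
    kept = [
        r for r in records if include_all or (r.cc_len > 0 and r.rep_len > 0)
    ]
    if not kept:
        raise ValueError("no proteins with both CC segments and repeat runs")
    n = len(kept)
    obs_ge = sum(r.observed_overlap >= overlap_threshold for r in kept)
    exp_ge = sum(r.expected_overlap >= overlap_threshold for r in kept)
    if exp_ge in (0, n):
        return EnrichmentResult(
            observed=obs_ge, expected=float(exp_ge), ratio=math.nan,
            chi2=math.nan, p_value=math.nan,
            note="degenerate expected dichotomy: test undefined",
        )
    observed_cells = np.array([obs_ge, n - obs_ge], dtype=float)
    expected_cells = np.array([exp_ge, n - exp_ge], dtype=float)
    adj = np.maximum(np.abs(observed_cells - expected_cells) - 0.5, 0.0)
    chi2 = float((adj**2 / expected_cells).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentResult(
        observed=obs_ge, expected=float(exp_ge), ratio=obs_ge / exp_ge,
        chi2=chi2, p_value=p, method="chi2_yates_gof",
    )


# --------------------------------------------------------- scalar metrics


def a4_q4_ratio(summary: ProteomeSummary) -> float:
    """%A4 / %Q4 for one proteome; NaN when %Q4 is zero."""
    pct_q4 = summary.percent("Q4")
    if pct_q4 == 0:
        return math.nan
    return summary.percent("A4") / pct_q4


def normalized_overlap_metric(summary: ProteomeSummary) -> float:
    """%(Q4&A4) / (%A4)^2 with percentages on the 0-100 scale."""
    pct_a4 = summary.percent("A4")
    if pct_a4 == 0:
        return math.nan
    return summary.percent("Q4", "A4") / pct_a4**2


def phylo_correlation(points: Sequence[PhyloPoint]) -> CorrelationResult:
    """Pearson correlation of a metric with divergence times (mya)."""
    if len(points) < 3:
        raise ValueError("need at least 3 points for a correlation p-value")
    x = np.array([p.divergence_mya for p in points], dtype=float)
    y = np.array([p.value for p in points], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(
            r=math.nan, r_squared=math.nan, p_value=math.nan,
            n_points=len(points), note="constant input: correlation undefined",
        )
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(
        r=r, r_squared=r * r, p_value=float(res.pvalue), n_points=len(points)
    )


# ----------------------------------------------------------------- export


def results_to_json(results: Mapping[str, EnrichmentResult], path: str | Path) -> None:
    payload = {name: res.to_dict() for name, res in results.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def summaries_to_frame(summaries: Iterable[ProteomeSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])
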