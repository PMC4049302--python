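"""Proteome screen model: repeats x coiled coils, statsmodels-style.

:class:`ProteomeScreen` is built from protein records (plus optional
per-residue CC P-score tracks) and configured thresholds; ``fit()``
performs the full screen — repeat scanning and classification, CC
segment calling, class counting, co-occurrence and CC-association
enrichment tests, and the observed/expected >=4-residue CC/repeat
overlap test — returning a :class:`ScreenResults` that carries every
statistic with a ``summary()`` table and export/plot helpers.
:func:`run_screen` orchestrates multi-species file-based runs for the
command line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import coiledcoil as cc
from . import design as dsg
from . import enrichment as enr
from . import repeats as rp
from .records import ProteinRecord, read_fasta, write_fasta

logger = logging.getLogger("repeatcc")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a multi-species screen run."""

    proteomes: Mapping[str, str]  # species -> FASTA path
    tracks: Mapping[str, str] | None = None  # species -> track directory
    divergence_mya: Mapping[str, float] | None = None
    min_len: int = rp.DEFAULT_MIN_LEN
    p_threshold: float = cc.DEFAULT_P_THRESHOLD
    overlap_threshold: int = enr.DEFAULT_OVERLAP_THRESHOLD
    outdir: str = "screen_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.overlap_threshold < 1:
            raise ValueError("thresholds must be positive")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")


class ProteomeScreen:
    """Repeat/CC screening model for one proteome.

    Parameters
    ----------
    records:
        The proteome.
    tracks:
        Optional protein_id -> :class:`~repeatcc.coiledcoil.CCTrack`.
        Proteins without a track carry no CC segments (all-missing
        track semantics). When omitted entirely, CC-dependent
        statistics are skipped.
    """

    def __init__(
        self,
        records: Sequence[ProteinRecord],
        tracks: Mapping[str, cc.CCTrack] | None = None,
        species: str = "",
        min_len: int = rp.DEFAULT_MIN_LEN,
        p_threshold: float = cc.DEFAULT_P_THRESHOLD,
        overlap_threshold: int = enr.DEFAULT_OVERLAP_THRESHOLD,
    ) -> None:
        if not records:
            raise ValueError("empty proteome")
        self.records = list(records)
        self.tracks = dict(tracks) if tracks is not None else None
        self.species = species or (records[0].species or "unspecified")
        self.min_len = min_len
        self.p_threshold = p_threshold
        self.overlap_threshold = overlap_threshold

    @classmethod
    def from_fasta(cls, path: str | Path, species: str = "", **kwargs) -> "ProteomeScreen":
        return cls(read_fasta(path, species=species), species=species, **kwargs)

    def fit(self, method: str = "chi2_yates") -> "ScreenResults":
        runs = [r for rec in self.records for r in rp.scan_all(rec, self.min_len)]
        flags = [rp.classify_protein(rec, self.min_len) for rec in self.records]

        segments: list[cc.CCSegment] = []
        cc_flags: dict[str, bool] | None = None
        if self.tracks is not None:
            cc_flags = {}
            for rec in self.records:
                track = self.tracks.get(rec.id)
                segs = (
                    cc.call_cc_segments(track, self.p_threshold) if track else []
                )
                segments.extend(segs)
                cc_flags[rec.id] = bool(segs)

        summary = enr.summarize_proteome(flags, cc_flags, species=self.species)

        tests: dict[str, enr.EnrichmentResult] = {}
        for a, b in (("Q4", "A4"), ("Q4", "QA4"), ("A4", "QA4")):
            tests[f"{a}+{b}"] = enr.cooccurrence_test(
                summary.count(a), summary.count(b), summary.count(a, b),
                summary.n_proteins, method=method,
            )
        if cc_flags is not None:
            for klass in ("Q4", "A4", "QA4"):
                tests[f"CC+{klass}"] = enr.cc_association_test(summary, klass, method)

        overlap_tests: dict[str, enr.EnrichmentResult] = {}
        overlap_records: dict[str, list[enr.OverlapRecord]] = {}
        if cc_flags is not None:
            lengths = {rec.id: len(rec.seq) for rec in self.records}
            seg_by_prot: dict[str, list[cc.CCSegment]] = {}
            for seg in segments:
                seg_by_prot.setdefault(seg.protein_id, []).append(seg)
            cc_masks = {
                pid: cc.cc_mask(segs, lengths[pid])
                for pid, segs in seg_by_prot.items()
            }
            for label, kinds in (
                ("all", ("Q", "A", "QA")), ("Q", ("Q",)), ("A", ("A",)), ("QA", ("QA",)),
            ):
                rep_masks: dict[str, set[int]] = {}
                for run in runs:
                    if run.kind in kinds:
                        rep_masks.setdefault(run.protein_id, set()).update(
                            range(run.start, run.end)
                        )
                recs = enr.build_overlap_records(lengths, rep_masks, cc_masks)
                overlap_records[label] = recs
                try:
                    overlap_tests[label] = enr.overlap_class_test(
                        recs, self.overlap_threshold
                    )
                except ValueError:
                    pass  # no protein carries both features; test undefined

        return ScreenResults(
            model=self, runs=runs, flags=flags, segments=segments,
            summary_counts=summary, cooccurrence=tests,
            overlap_tests=overlap_tests, overlap_records=overlap_records,
        )


@dataclass(frozen=True)
class ScreenResults:
    """Fitted screen: counts, enrichment and overlap statistics."""

    model: ProteomeScreen
    runs: list[rp.RepeatRun]
    flags: list[rp.RepeatFlags]
    segments: list[cc.CCSegment]
    summary_counts: enr.ProteomeSummary
    cooccurrence: dict[str, enr.EnrichmentResult]
    overlap_tests: dict[str, enr.EnrichmentResult]
    overlap_records: dict[str, list[enr.OverlapRecord]]

    @property
    def a4_q4_ratio(self) -> float:
        return enr.a4_q4_ratio(self.summary_counts)

    @property
    def normalized_overlap(self) -> float:
        return enr.normalized_overlap_metric(self.summary_counts)

    def summary(self) -> str:
        """Human-readable screen report (headline numbers)."""
        s = self.summary_counts
        lines = [
            f"Proteome screen: {s.species}",
            "=" * 46,
            f"proteins: {s.n_proteins}",
        ]
        for klass in ("Q4", "A4", "QA4", "CC"):
            lines.append(
                f"  {klass:<4} {s.count(klass):>7}  ({s.percent(klass):6.2f} %)"
            )
        lines.append(f"  %A4/%Q4 ratio:        {self.a4_q4_ratio:8.3f}")
        lines.append(f"  %(Q4&A4)/(%A4)^2:     {self.normalized_overlap:8.4f}")
        lines.append("")
        lines.append("enrichment (observed / expected, Yates chi2):")
        for name, res in {**self.cooccurrence}.items():
            lines.append(
                f"  {name:<8} obs={res.observed:<6} exp={res.expected:8.2f} "
                f"ratio={res.ratio:6.2f}  p={res.p_value:.3g}"
            )
        for label, res in self.overlap_tests.items():
            lines.append(
                f"  overlap>={self.model.overlap_threshold} [{label:<3}] "
                f"obs={res.observed:<6} exp={res.expected:8.2f} "
                f"ratio={res.ratio:6.2f}  p={res.p_value:.3g}"
            )
        return "\n".join(lines)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        frames = {
            "runs": rp.runs_to_frame(self.runs),
            "flags": rp.flags_to_frame(self.flags),
            "summary": enr.summaries_to_frame([self.summary_counts]),
            "enrichment": pd.DataFrame(
                [{"test": k, **v.to_dict()} for k, v in self.cooccurrence.items()]
            ),
        }
        if self.segments:
            frames["segments"] = cc.segments_to_frame(self.segments)
        if self.overlap_tests:
            frames["overlap_tests"] = pd.DataFrame(
                [{"repeat_kind": k, **v.to_dict()} for k, v in self.overlap_tests.items()]
            )
        return frames

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prefix = self.summary_counts.species or "proteome"
        for name, frame in self.to_frames().items():
            frame.to_csv(outdir / f"{prefix}.{name}.tsv", sep="\t", index=False)
        (outdir / f"{prefix}.venn.json").write_text(
            json.dumps(self.summary_counts.venn_counts(), indent=2) + "\n"
        )

    def plot_occurrence(self, ax=None):
        """Bar plot of Q4/A4/QA4 (and CC) percent occurrence."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.summary_counts
        classes = ["Q4", "A4", "QA4"] + (["CC"] if s.count("CC") else [])
        ax.bar(classes, [s.percent(k) for k in classes],
               color=["crimson", "seagreen", "gold", "steelblue"][: len(classes)])
        ax.set_ylabel("% of proteins")
        ax.set_title(f"repeat/CC occurrence: {s.species}")
        return ax


# ------------------------------------------------------------- orchestration


def load_tracks_dir(
    directory: str | Path, records: Sequence[ProteinRecord]
) -> dict[str, cc.CCTrack]:
    """Read ``<protein_id>.track`` files for every record that has one."""
    directory = Path(directory)
    tracks = {}
    for rec in records:
        path = directory / f"{rec.id}.track"
        if path.exists():
            tracks[rec.id] = cc.parse_cc_track(
                path.read_text(), rec.id, len(rec.seq), seq=rec.seq
            )
    return tracks


def run_screen(config: RunConfig) -> dict[str, ScreenResults]:
    """Execute the full multi-species screen and write report files.

    Per species: scan -> classify -> (tracks) -> segments -> summary ->
    co-occurrence tests -> CC association -> overlap tests -> ratio and
    normalized metrics; then cross-species phylogenetic correlations
    when a divergence-time table is configured. Missing track
    directories skip the CC stages for that species with a warning.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, ScreenResults] = {}
    for species, fasta in config.proteomes.items():
        records = read_fasta(fasta, species=species)
        logger.info("%s: %d proteins from %s", species, len(records), fasta)
        tracks = None
        track_dir = (config.tracks or {}).get(species)
        if track_dir is not None:
            if Path(track_dir).is_dir():
                tracks = load_tracks_dir(track_dir, records)
                logger.info("%s: %d CC tracks", species, len(tracks))
            else:
                logger.warning(
                    "%s: track directory %s missing; CC stages skipped",
                    species, track_dir,
                )
        model = ProteomeScreen(
            records, tracks=tracks, species=species,
            min_len=config.min_len, p_threshold=config.p_threshold,
            overlap_threshold=config.overlap_threshold,
        )
        res = model.fit()
        res.write(outdir)
        for line in res.summary().splitlines():
            logger.info("%s", line)
        results[species] = res

    summary_frame = enr.summaries_to_frame(
        [r.summary_counts for r in results.values()]
    )
    summary_frame["a4_q4_ratio"] = [r.a4_q4_ratio for r in results.values()]
    summary_frame["normalized_overlap"] = [
        r.normalized_overlap for r in results.values()
    ]
    summary_frame.to_csv(outdir / "species_summary.tsv", sep="\t", index=False)

    if config.divergence_mya:
        correlations = {}
        for metric in ("a4_q4_ratio", "normalized_overlap"):
            points = [
                enr.PhyloPoint(sp, config.divergence_mya[sp],
                               float(summary_frame.loc[summary_frame.species == sp, metric].iloc[0]))
                for sp in results
                if sp in config.divergence_mya
            ]
            if len(points) >= 3:
                corr = enr.phylo_correlation(points)
                correlations[metric] = {
                    "r": corr.r, "r_squared": corr.r_squared,
                    "p_value": corr.p_value, "n_points": corr.n_points,
                    "note": corr.note,
                }
                logger.info(
                    "phylo correlation %s: r=%.3f r2=%.3f p=%.3g",
                    metric, corr.r, corr.r_squared, corr.p_value,
                )
        (outdir / "phylo_correlations.json").write_text(
            json.dumps(correlations, indent=2) + "\n"
        )
    return results


def run_design(
    base_fasta: str | Path,
    register_anchors: Sequence[int],
    design_spec: Mapping,
    outdir: str | Path,
    use_naive_scorer: bool = True,
) -> list[dsg.DesignVariant]:
    """Generate cc+/cc-/polyA-length variants of the first FASTA record.

    ``design_spec`` is a mapping with optional keys:

    * ``region``: [start, end) of the repeat region to mutate
      (default: span of all Q/A/QA runs);
    * ``cc_plus``: {"n_heptads": int, "overrides": {index: letter}};
    * ``cc_minus``: {"n_sites": int};
    * ``polyA_deltas``: list of signed residue counts applied to the
      longest alanine run.

    Writes a variant FASTA, a substitutions TSV, a register report JSON
    and (optionally) per-variant naive CC propensity minima over the
    target region.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = read_fasta(base_fasta)[0]
    seq = record.seq
    register = dsg.assign_register(seq, list(register_anchors))
    if register.unsatisfied_anchors:
        logger.warning(
            "register frame %d leaves anchors %s off a/d positions",
            register.frame, register.unsatisfied_anchors,
        )

    runs = rp.scan_all(record)
    if "region" in design_spec:
        region = tuple(design_spec["region"])
    elif runs:
        region = (min(r.start for r in runs), max(r.end for r in runs))
    else:
        raise dsg.DesignError("no repeat runs found and no region given")

    variants: list[dsg.DesignVariant] = []
    if "cc_plus" in design_spec:
        cp = design_spec["cc_plus"]
        overrides = {int(k): v for k, v in cp.get("overrides", {}).items()} or None
        variants.append(
            dsg.design_cc_plus(
                seq, register, region, cp["n_heptads"], overrides=overrides,
                base_id=record.id, variant_id=f"{record.id}/cc+",
            )
        )
    if "cc_minus" in design_spec:
        variants.append(
            dsg.design_cc_minus(
                seq, register, region, design_spec["cc_minus"]["n_sites"],
                base_id=record.id, variant_id=f"{record.id}/cc-",
            )
        )
    for delta in design_spec.get("polyA_deltas", []):
        a_runs = [r for r in runs if r.kind == "A"]
        if not a_runs:
            raise dsg.DesignError("no alanine run to expand or contract")
        longest = max(a_runs, key=lambda r: r.length)
        variants.append(
            dsg.polyA_length_variant(
                seq, longest, int(delta),
                base_id=record.id, variant_id=f"{record.id}/{int(delta):+d}A",
            )
        )

    write_fasta(
        [ProteinRecord(v.variant_id.replace("/", "_"), v.seq) for v in variants],
        outdir / "variants.fasta",
    )
    sub_rows = [
        {"variant_id": v.variant_id, "index0": i, "old": o, "new": n}
        for v in variants for i, o, n in v.substitutions
    ]
    pd.DataFrame(sub_rows, columns=["variant_id", "index0", "old", "new"]).to_csv(
        outdir / "substitutions.tsv", sep="\t", index=False
    )
    report: dict = {"base_id": record.id, "register": register.to_dict()}
    if use_naive_scorer:
        import numpy as np

        def region_min_pseudo_p(s: str) -> float:
            scores = cc.naive_heptad_score(s)
            window = scores[region[0]: min(region[1], len(s))]
            finite = window[~np.isnan(window)]
            return float(finite.min()) if finite.size else float("nan")

        report["naive_min_pseudo_p"] = {
            "base": region_min_pseudo_p(seq),
            **{v.variant_id: region_min_pseudo_p(v.seq) for v in variants},
        }
    (outdir / "design_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return variants
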