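"""Synthetic proteomes, CC tracks, phylo series and CD fixtures.

Every generator is a pure function of its spec plus a seed, and each
emits ground truth that the corresponding analysis stage must recover
(closure). The proteome generator emulates the statistical structure of
the screened reference proteomes: variable proteome size, a log-normal
protein length law, SwissProt-like background residue usage, planted
per-protein Q4/A4/QA4 repeats with a tunable co-occurrence enrichment
factor, and planted CC segments with a tunable repeat-overlap bias.
Accidental Q/A/QA runs in the background are suppressed by rejection so
planted prevalences are exact ground truth.

Default planted prevalences follow the human-proteome occurrences
reported for Q4 (2.29%) and A4 (7.73%); QA4 prevalence and the
co-occurrence factor are not printed as numbers and default to 2% and
2.0 (a clear but moderate over-representation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cd import CDMeta, CDSpectrum, MeltCurve
from .coiledcoil import CCSegment, CCTrack
from .enrichment import PhyloPoint
from .records import ProteinRecord
from .repeats import RepeatRun, classify_protein

#: SwissProt-like background amino-acid frequencies (fractions)
BACKGROUND_FREQS: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: example divergence times from Homo sapiens (mya), TimeTree-style;
#: user-editable input, not a package result
EXAMPLE_DIVERGENCE_MYA: dict[str, float] = {
    "Homo": 0.0, "Mus": 90.0, "Xenopus": 352.0,
    "Drosophila": 736.0, "Caenorhabditis": 797.0, "Saccharomyces": 1105.0,
}


def child_seeds(root_seed: int, n: int) -> list[int]:
    """Fan a root seed out to ``n`` independent child seeds (< 2**31).

    Uses numpy's SeedSequence spawning so children are decorrelated and
    reproducible across platforms.
    """
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


@dataclass(frozen=True)
class ProteomeSpec:
    """Parameters of a planted-repeat synthetic proteome."""

    n_proteins: int = 20_000
    length_log_mean: float = 5.93  # log-normal of protein length, ~375 aa median
    length_log_sd: float = 0.65
    length_min: int = 60
    length_max: int = 5_000
    p_Q4: float = 0.0229
    p_A4: float = 0.0773
    p_QA4: float = 0.02
    cooccurrence_factor: float = 2.0  # multiplier on P(Q4 & A4) vs independence
    repeat_len_geom_p: float = 0.35  # planted run length = 4 + Geometric - 1
    min_len: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_Q4, self.p_A4, self.p_QA4):
            if not 0 <= p <= 1:
                raise ValueError("planted probabilities must lie in [0, 1]")
        f = self.cooccurrence_factor
        p11 = f * self.p_Q4 * self.p_A4
        if f < 0 or p11 > min(self.p_Q4, self.p_A4):
            raise ValueError(
                f"infeasible co-occurrence factor {f}: joint probability "
                f"{p11:.4g} exceeds a marginal"
            )


@dataclass(frozen=True)
class CCPlantSpec:
    """Parameters of planted coiled-coil segments."""

    p_cc: float = 0.1
    seg_len_min: int = 21
    seg_len_max: int = 49
    overlap_bias: float = 0.0  # probability a segment is centered on a repeat
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_cc <= 1 or not 0 <= self.overlap_bias <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if not 1 <= self.seg_len_min <= self.seg_len_max:
            raise ValueError("invalid segment length law")


@dataclass
class ProteomeTruth:
    """Ground truth emitted alongside a generated proteome."""

    flags: pd.DataFrame  # protein_id, has_Q4, has_A4, has_QA4
    runs: list[RepeatRun] = field(default_factory=list)

    def runs_for(self, protein_id: str) -> list[RepeatRun]:
        return [r for r in self.runs if r.protein_id == protein_id]


# ------------------------------------------------------------ flag drawing


def draw_repeat_flags(spec: ProteomeSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Per-protein Q4/A4/QA4 membership with the planted joint structure.

    Q4 and A4 are drawn jointly with P(Q4 & A4) = f * p_Q4 * p_A4 and
    the stated marginals; QA4 is independent. This fast path is exact
    for membership statistics and is what the sequence generator itself
    consumes.
    """
    n = spec.n_proteins
    p11 = spec.cooccurrence_factor * spec.p_Q4 * spec.p_A4
    probs = [
        p11,                      # Q4 and A4
        spec.p_Q4 - p11,          # Q4 only
        spec.p_A4 - p11,          # A4 only
        1 - spec.p_Q4 - spec.p_A4 + p11,
    ]
    cell = rng.choice(4, size=n, p=probs)
    has_q = (cell == 0) | (cell == 1)
    has_a = (cell == 0) | (cell == 2)
    has_qa = rng.random(n) < spec.p_QA4
    return pd.DataFrame(
        {
            "protein_id": [f"SYN{i:06d}" for i in range(n)],
            "has_Q4": has_q,
            "has_A4": has_a,
            "has_QA4": has_qa,
        }
    )


# --------------------------------------------------------- sequence drawing

_LETTERS = np.array(list(BACKGROUND_FREQS))
_FREQS = np.array(list(BACKGROUND_FREQS.values()))
_FREQS = _FREQS / _FREQS.sum()
_NONQA = np.array([ch for ch in BACKGROUND_FREQS if ch not in "QA"])
_NONQA_F = np.array([BACKGROUND_FREQS[ch] for ch in _NONQA])
_NONQA_F = _NONQA_F / _NONQA_F.sum()


def _suppress_accidental_runs(
    seq: np.ndarray, min_len: int, rng: np.random.Generator
) -> None:
    """Break accidental Q4/A4/QA4 runs in-place with non-Q/A letters."""
    from .repeats import scan_homopolymer, scan_qa_alternation

    while True:
        s = "".join(seq)
        runs = (
            scan_homopolymer(s, "Q", min_len)
            + scan_homopolymer(s, "A", min_len)
            + scan_qa_alternation(s, min_len)
        )
        if not runs:
            return
        for run in runs:
            mid = (run.start + run.end) // 2
            seq[mid] = rng.choice(_NONQA, p=_NONQA_F)


def _planted_run_length(spec: ProteomeSpec, rng: np.random.Generator) -> int:
    return spec.min_len + int(rng.geometric(spec.repeat_len_geom_p)) - 1


def _place_runs(
    L: int, lengths: Sequence[int], rng: np.random.Generator, max_tries: int = 200
) -> list[int]:
    """Random starts such that runs plus 1-residue margins are disjoint."""
    for _ in range(max_tries):
        starts = [int(rng.integers(1, L - l)) for l in lengths]
        intervals = sorted(
            (s - 1, s + l + 1) for s, l in zip(starts, lengths)
        )
        if all(b0 <= a1 for (_, b0), (a1, _) in zip(intervals, intervals[1:])):
            return starts
    raise ValueError(f"could not place runs of lengths {list(lengths)} in {L} residues")


def _run_content(kind: str, length: int) -> str:
    if kind == "Q":
        return "Q" * length
    if kind == "A":
        return "A" * length
    return ("QA" * length)[:length]  # strict alternation starting with Q


def generate_proteome(spec: ProteomeSpec) -> tuple[list[ProteinRecord], ProteomeTruth]:
    """Generate a proteome with planted repeats and exact ground truth.

    Deterministic given ``spec.seed``. Each protein's background is
    drawn from the background frequencies with accidental Q4/A4/QA4
    runs suppressed, then the planted runs are written at random
    non-adjacent positions with run-breaking flanking residues, so
    re-scanning recovers exactly the planted flags and run coordinates.
    """
    seeds = child_seeds(spec.seed, 3)
    rng_flags = np.random.default_rng(seeds[0])
    rng_seq = np.random.default_rng(seeds[1])

    flags = draw_repeat_flags(spec, rng_flags)
    lengths = np.exp(
        rng_seq.normal(spec.length_log_mean, spec.length_log_sd, spec.n_proteins)
    )
    lengths = np.clip(lengths.astype(int), spec.length_min, spec.length_max)

    records: list[ProteinRecord] = []
    truth_runs: list[RepeatRun] = []
    for i, row in enumerate(flags.itertuples()):
        pid = row.protein_id
        kinds = [
            k for k, has in (("Q", row.has_Q4), ("A", row.has_A4), ("QA", row.has_QA4))
            if has
        ]
        for attempt in range(30):
            L = int(lengths[i])
            seq = rng_seq.choice(_LETTERS, size=L, p=_FREQS)
            _suppress_accidental_runs(seq, spec.min_len, rng_seq)
            run_lengths = [_planted_run_length(spec, rng_seq) for _ in kinds]
            if sum(run_lengths) + 3 * len(kinds) + 2 >= L:
                lengths[i] = min(spec.length_max, L * 2)  # too short to host runs
                continue
            starts = _place_runs(L, run_lengths, rng_seq)
            planted = []
            for kind, start, rl in zip(kinds, starts, run_lengths):
                seq[start : start + rl] = list(_run_content(kind, rl))
                seq[start - 1] = rng_seq.choice(_NONQA, p=_NONQA_F)
                if start + rl < L:
                    seq[start + rl] = rng_seq.choice(_NONQA, p=_NONQA_F)
                planted.append(RepeatRun(pid, kind, start, start + rl))
            record = ProteinRecord(pid, "".join(seq), species="synthetic")
            got = classify_protein(record, spec.min_len)
            if (got.has_Q4, got.has_A4, got.has_QA4) == (
                bool(row.has_Q4), bool(row.has_A4), bool(row.has_QA4)
            ):
                records.append(record)
                truth_runs.extend(planted)
                break
        else:
            raise RuntimeError(f"could not realize planted flags for {pid}")
    return records, ProteomeTruth(flags=flags, runs=truth_runs)


# -------------------------------------------------------------- CC planting


def generate_cc_tracks(
    records: Sequence[ProteinRecord],
    truth: ProteomeTruth,
    plant: CCPlantSpec,
) -> tuple[dict[str, CCTrack], list[CCSegment]]:
    """Plant per-protein CC segments and emit P-score tracks.

    Planted segments receive P ~ Uniform(0, 0.04); everywhere else
    P ~ Uniform(0.2, 1), so calling segments at the 0.05 threshold
    recovers the planted boundaries exactly. With overlap bias beta, a
    planted segment is centered on one of the protein's planted repeat
    runs (when any exist) instead of being placed uniformly.
    """
    rng = np.random.default_rng(plant.seed)
    tracks: dict[str, CCTrack] = {}
    planted: list[CCSegment] = []
    for rec in records:
        L = len(rec.seq)
        p = rng.uniform(0.2, 1.0, size=L)
        if rng.random() < plant.p_cc:
            seg_len = int(rng.integers(plant.seg_len_min, plant.seg_len_max + 1))
            while seg_len > L and seg_len > 8:
                seg_len = max(8, seg_len // 2)  # resample shorter for tiny proteins
            if seg_len <= L:
                runs = truth.runs_for(rec.id)
                if runs and rng.random() < plant.overlap_bias:
                    run = runs[int(rng.integers(len(runs)))]
                    center = (run.start + run.end) // 2
                    start = int(np.clip(center - seg_len // 2, 0, L - seg_len))
                else:
                    start = int(rng.integers(0, L - seg_len + 1))
                scores = rng.uniform(0.0, 0.04, size=seg_len)
                p[start : start + seg_len] = scores
                planted.append(
                    CCSegment(rec.id, start, start + seg_len, float(scores.min()))
                )
        tracks[rec.id] = CCTrack(rec.id, p)
    return tracks, planted


# -------------------------------------------------------------- phylo series


def generate_phylo_series(
    n_species: int = 6,
    slope: float = -0.002,
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 3.0,
    mya: Sequence[float] | None = None,
) -> list[PhyloPoint]:
    """Metric-vs-divergence points: value = intercept + slope*mya + noise."""
    if mya is None:
        mya = np.linspace(0.0, 1100.0, n_species)
    else:
        mya = np.asarray(mya, dtype=float)
        n_species = len(mya)
    rng = np.random.default_rng(seed)
    values = intercept + slope * np.asarray(mya) + rng.normal(0, noise_sd, n_species)
    return [
        PhyloPoint(f"sp{i}", float(m), float(v))
        for i, (m, v) in enumerate(zip(mya, values))
    ]


# --------------------------------------------------------------- CD fixtures


def _gaussian(w: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - center) / width) ** 2)


def generate_cd_fixture(
    helix_weight: float,
    cc_ratio_target: float = 1.10,
    noise_sd: float = 0.0,
    meta: CDMeta | None = None,
    seed: int = 0,
    depth_mre: float = -30_000.0,
) -> tuple[CDSpectrum, float]:
    """A raw-mdeg spectrum whose MRE reduction has a known 222/208 ratio.

    The helix basis is a two-Gaussian combination with minima at 208 and
    222 nm solved so that MRE(208) = ``depth_mre`` and MRE(222) =
    ``depth_mre * cc_ratio_target``; the coil basis is a single minimum
    at 200 nm. The spectrum is ``h * helix + (1 - h) * coil`` plus
    Gaussian noise, converted back to raw mdeg via the metadata so that
    the MRE reduction round-trips. Returns (spectrum, planted ratio of
    the helix basis). This is a basis-combination fixture, not a
    physical CD model.
    """
    if not 0 <= helix_weight <= 1:
        raise ValueError("helix_weight must lie in [0, 1]")
    if meta is None:
        meta = CDMeta(mw=3000.0, n_residues=31, conc_mg_ml=0.2, path_cm=0.01)
    w = np.arange(195.0, 260.5, 0.5)
    g208, g222 = _gaussian(w, 208, 6.0), _gaussian(w, 222, 6.0)
    # solve c1*g208 + c2*g222 at 208 nm = depth, at 222 nm = depth*target
    A = np.array(
        [[1.0, _gaussian(np.array([208.0]), 222, 6.0)[0]],
         [_gaussian(np.array([222.0]), 208, 6.0)[0], 1.0]]
    )
    b = np.array([depth_mre, depth_mre * cc_ratio_target])
    c1, c2 = np.linalg.solve(A.T, b)  # rows: value at 208, at 222
    helix = c1 * g208 + c2 * g222
    coil = 1.3 * depth_mre * _gaussian(w, 200, 7.0)
    mre = helix_weight * helix + (1 - helix_weight) * coil
    rng = np.random.default_rng(seed)
    mre = mre + rng.normal(0, noise_sd, mre.size)
    # invert the MRE formula to raw instrument mdeg
    theta_raw = mre * 10.0 * (meta.n_residues - 1) * meta.conc_mg_ml * meta.path_cm / meta.mw
    return CDSpectrum(w, theta_raw, meta, units="mdeg"), cc_ratio_target


def generate_melt_fixture(
    t_mid: float = 45.0,
    width: float = 8.0,
    theta_folded: float = -22_000.0,
    theta_unfolded: float = -2_000.0,
    temperatures: Sequence[float] | None = None,
) -> MeltCurve:
    """Sigmoid 222-nm melt fixture with a known folded baseline at 5 degC."""
    t = np.asarray(
        temperatures if temperatures is not None else np.arange(5.0, 76.0, 5.0)
    )
    frac = 1.0 / (1.0 + np.exp((t - t_mid) / width))
    theta = theta_unfolded + (theta_folded - theta_unfolded) * frac
    return MeltCurve(t, theta)
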