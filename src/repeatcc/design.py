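"""Structure-guided coiled-coil mutagenesis of repeat regions.

The heptad register (positions a-g, with a/d forming the hydrophobic
core) is anchored on user-asserted a/d residues — typically the valines
immediately flanking a polyQ/polyA region — and sequence variants are
generated by substituting a/d positions inside a target region:

* cc+ variants place canonical CC-stabilizing hydrophobics (L at a,
  V at d by default) to enhance coiled-coil propensity;
* cc- variants place CC-breaking prolines at a/d;
* polyA length variants expand or contract an alanine run, emulating
  the +6A/+12A expansions and -6A/-12A deletions studied in
  polyA-expansion disease models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .repeats import RepeatRun

HEPTAD_LETTERS = "abcdefg"
#: heptad indices of the hydrophobic core
CORE_POSITIONS = (0, 3)  # a and d


class DesignError(ValueError):
    """Raised for infeasible register or variant requests."""


@dataclass(frozen=True)
class HeptadRegister:
    """A heptad frame over a region of one sequence.

    ``frame`` gives the heptad position (a=0 ... g=6) of sequence index
    0, so index ``i`` sits at heptad position ``(i + frame) % 7``.
    """

    frame: int
    region: tuple[int, int]
    unsatisfied_anchors: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.frame <= 6:
            raise DesignError("frame must be in 0..6")

    def position(self, i: int) -> int:
        return (i + self.frame) % 7

    def letter(self, i: int) -> str:
        return HEPTAD_LETTERS[self.position(i)]

    def is_core(self, i: int) -> bool:
        return self.position(i) in CORE_POSITIONS

    def core_indices(self, start: int, end: int) -> list[int]:
        """a/d positions within [start, end), in order."""
        return [i for i in range(start, end) if self.is_core(i)]

    def to_dict(self) -> dict:
        return {
            "frame": self.frame,
            "region": list(self.region),
            "position_of_index0": HEPTAD_LETTERS[self.frame],
            "unsatisfied_anchors": list(self.unsatisfied_anchors),
        }


@dataclass(frozen=True)
class DesignVariant:
    """A sequence variant plus the edits that produced it."""

    base_id: str
    variant_id: str
    base_seq: str
    seq: str
    substitutions: tuple[tuple[int, str, str], ...] = ()
    indels: tuple[tuple[int, str], ...] = ()  # (index, +inserted / -deleted)
    note: str = ""

    def __post_init__(self) -> None:
        if self.apply_edits(self.base_seq) != self.seq:
            raise DesignError("recorded edits do not reproduce the variant sequence")

    def apply_edits(self, base: str) -> str:
        """Re-apply the recorded substitutions and indels to ``base``."""
        s = list(base)
        for idx, old, new in self.substitutions:
            if s[idx] != old:
                raise DesignError(
                    f"substitution at {idx} expected {old!r}, found {s[idx]!r}"
                )
            s[idx] = new
        out = "".join(s)
        for idx, edit in self.indels:
            if edit.startswith("+"):
                out = out[:idx] + edit[1:] + out[idx:]
            elif edit.startswith("-"):
                frag = edit[1:]
                if out[idx : idx + len(frag)] != frag:
                    raise DesignError(f"deletion at {idx} does not match {frag!r}")
                out = out[:idx] + out[idx + len(frag):]
            else:
                raise DesignError(f"malformed indel record {edit!r}")
        return out


def assign_register(
    seq: str,
    anchor_indices: Sequence[int],
    region: tuple[int, int] | None = None,
) -> HeptadRegister:
    """Heptad frame maximizing the number of anchors on a/d positions.

    Anchors are sequence indices asserted to occupy core (a or d)
    positions, e.g. flanking valines. Of the seven candidate frames the
    one satisfying the most anchors wins; ties break to the smallest
    frame. Anchors the winning frame leaves off-core are reported in
    ``unsatisfied_anchors`` rather than raising.
    """
    if not anchor_indices:
        raise DesignError("at least one register anchor is required")
    for a in anchor_indices:
        if not 0 <= a < len(seq):
            raise DesignError(f"anchor index {a} outside sequence of length {len(seq)}")
    best_frame, best_hits = 0, -1
    for frame in range(7):
        hits = sum((a + frame) % 7 in CORE_POSITIONS for a in anchor_indices)
        if hits > best_hits:
            best_frame, best_hits = frame, hits
    reg_region = region if region is not None else (0, len(seq))
    unsatisfied = tuple(
        a for a in anchor_indices if (a + best_frame) % 7 not in CORE_POSITIONS
    )
    return HeptadRegister(best_frame, reg_region, unsatisfied)


def _core_substitutions(
    seq: str,
    register: HeptadRegister,
    target_region: tuple[int, int],
    n_sites: int,
    palette: Mapping[int, str],
    overrides: Mapping[int, str] | None = None,
) -> list[tuple[int, str, str]]:
    start, end = target_region
    rstart, rend = register.region
    if not (rstart <= start <= end <= rend):
        raise DesignError("target_region must lie within the register's region")
    core = register.core_indices(start, end)
    if len(core) < n_sites:
        raise DesignError(
            f"region [{start},{end}) offers only {len(core)} a/d sites, "
            f"need {n_sites}"
        )
    subs = []
    for idx in core[:n_sites]:
        new = (overrides or {}).get(idx, palette[register.position(idx)])
        subs.append((idx, seq[idx], new))
    return subs


def design_cc_plus(
    seq: str,
    register: HeptadRegister,
    target_region: tuple[int, int],
    n_heptads: int,
    palette: Mapping[int, str] | None = None,
    overrides: Mapping[int, str] | None = None,
    base_id: str = "base",
    variant_id: str = "cc+",
) -> DesignVariant:
    """CC-stabilized variant: L/V at a/d of ``n_heptads`` heptads.

    Substitutes the first ``2 * n_heptads`` a/d positions inside
    ``target_region`` (two core sites per heptad), a -> L and d -> V by
    default; per-site ``overrides`` reproduce published mutants exactly.
    Sequence length is unchanged. A variant whose substitutions are all
    no-ops is returned with a "zero-change" note.
    """
    pal = {0: "L", 3: "V"} if palette is None else dict(palette)
    subs = _core_substitutions(
        seq, register, target_region, 2 * n_heptads, pal, overrides
    )
    return _finish_variant(seq, subs, base_id, variant_id)


def design_cc_minus(
    seq: str,
    register: HeptadRegister,
    target_region: tuple[int, int],
    n_sites: int,
    base_id: str = "base",
    variant_id: str = "cc-",
) -> DesignVariant:
    """CC-destabilized variant: prolines at ``n_sites`` a/d positions."""
    subs = _core_substitutions(
        seq, register, target_region, n_sites, {0: "P", 3: "P"}
    )
    return _finish_variant(seq, subs, base_id, variant_id)


def _finish_variant(
    seq: str, subs: list[tuple[int, str, str]], base_id: str, variant_id: str
) -> DesignVariant:
    effective = tuple((i, o, n) for i, o, n in subs if o != n)
    s = list(seq)
    for i, _, n in effective:
        s[i] = n
    note = "zero-change variant: region already bears the palette letters" \
        if subs and not effective else ""
    return DesignVariant(
        base_id=base_id, variant_id=variant_id, base_seq=seq,
        seq="".join(s), substitutions=effective, note=note,
    )


def polyA_length_variant(
    seq: str,
    run: RepeatRun,
    delta: int,
    base_id: str = "base",
    variant_id: str | None = None,
) -> DesignVariant:
    """Expand (delta > 0) or contract (delta < 0) an alanine run.

    Insertions are placed at the C-terminal end of the run (placement
    within a homopolymer is unobservable in the product); deletions
    remove the run's last ``|delta|`` alanines. Downstream coordinates
    shift by ``delta``. Re-scanning the variant yields a run of length
    ``run.length + delta`` (or none, when the run is eliminated).
    """
    if run.kind != "A" or set(seq[run.start : run.end]) != {"A"}:
        raise DesignError("run must be an alanine homopolymer of this sequence")
    if delta < -run.length:
        raise DesignError(
            f"cannot delete {-delta} residues from a {run.length}-residue run"
        )
    vid = variant_id if variant_id is not None else f"{delta:+d}A"
    if delta == 0:
        return DesignVariant(base_id, vid, seq, seq, note="identity variant")
    if delta > 0:
        indel = (run.end, "+" + "A" * delta)
        new_seq = seq[: run.end] + "A" * delta + seq[run.end :]
    else:
        indel = (run.end + delta, "-" + "A" * (-delta))
        new_seq = seq[: run.end + delta] + seq[run.end :]
    return DesignVariant(
        base_id, vid, seq, new_seq, indels=(indel,),
    )
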