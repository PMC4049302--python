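"""Synthetic reconstructions of the coiled-coil study peptides.

These sequences are reconstructions assembled from the published
*textual* description of the peptide panel, not verbatim transcriptions
(the originals are printed only as figure artwork):

* ``RUNX2_CCD`` — the polyQ/polyA coiled-coil domain of human RUNX2
  (residues K24–D84 of the short isoform, i.e. the UniProt Q13950
  Q/A-domain region), preceded by a YK dipeptide added for
  spectrophotometric concentration measurement (Y) and solubility (K).
  Its core is a 23-glutamine run and a 17-alanine run separated by a
  single glutamate — about two-thirds of the 61-residue domain — with
  valines at a/d heptad positions immediately flanking the repeat
  region and scattered prolines/charged residues in the flanks.
* ``CC_HOST_NTERM``/``CC_HOST_CTERM`` — a four-heptad model coiled-coil
  host (two heptads per side) into which guest repeat tracts are
  inserted; the host heptad ``EVSALEK`` carries V at position a and L
  at position d under ``MODEL_REGISTER_FRAME``.
* ``ccAA``/``ccA21``/``ccA7``/``ccQQ``/``ccQ_A``/``ccA_QA`` — host
  peptides with 14A, 21A, 7A, 14Q, 7Q+7A and 7A+QAQAQAQ guests.
* ``ccAL``/``ccAP`` — ccAA with CC-stabilizing L/V, or CC-breaking P,
  substitutions at the a/d positions of the two polyA heptads.

The worked-example quantities asserted downstream (maximal runs of 23Q
and 17A separated by one residue; maximal A runs of 14 and 21) depend
only on the textually stated composition, which the reconstruction
preserves exactly.
"""

from __future__ import annotations

from .design import HeptadRegister

# RUNX2 Q/A coiled-coil domain, K24-D84 numbering of the short isoform,
# with the YK solubility/quantification dipeptide prefix.
RUNX2_CCD_DOMAIN = (
    "KMSDVSPVVAA" + "Q" * 23 + "E" + "A" * 17 + "VPRLRPPHD"
)
RUNX2_CCD = "YK" + RUNX2_CCD_DOMAIN

#: indices (in RUNX2_CCD) of the valines flanking the polyQ/polyA region,
#: used as a/d register anchors
RUNX2_CCD_ANCHORS = (
    RUNX2_CCD.index("VVAAQ") + 1,      # V immediately preceding the repeats
    RUNX2_CCD.index("AVPRL", 20) + 1,  # V immediately following the repeats
)

# ---------------------------------------------------------- model peptides

_HOST_HEPTAD = "EVSALEK"  # V at a, L at d under frame 4
CC_HOST_NTERM = _HOST_HEPTAD * 2
CC_HOST_CTERM = _HOST_HEPTAD * 2
MODEL_PREFIX = "YK"
#: heptad frame of every model peptide: index 0 of the full sequence
#: (the prefix Y) sits at heptad position e, which lands each host V on
#: a, each host L on d, and the host E/K charges on e/g
MODEL_REGISTER_FRAME = 4


def model_peptide(guest: str) -> str:
    """Four-heptad host peptide with ``guest`` inserted at the core."""
    return MODEL_PREFIX + CC_HOST_NTERM + guest + CC_HOST_CTERM


def guest_region(guest: str) -> tuple[int, int]:
    """Half-open indices of the guest tract within :func:`model_peptide`."""
    start = len(MODEL_PREFIX) + len(CC_HOST_NTERM)
    return start, start + len(guest)


def model_register(guest: str) -> HeptadRegister:
    return HeptadRegister(MODEL_REGISTER_FRAME, (0, len(model_peptide(guest))))


ccA7 = model_peptide("A" * 7)
ccAA = model_peptide("A" * 14)
ccA21 = model_peptide("A" * 21)
ccQQ = model_peptide("Q" * 14)
ccQ_A = model_peptide("Q" * 7 + "A" * 7)
ccA_QA = model_peptide("A" * 7 + "QAQAQAQ")


def _substitute_guest_core(base_guest_len: int, a_letter: str, d_letter: str) -> str:
    """ccAA-style peptide with a/d positions of the guest replaced."""
    seq = list(model_peptide("A" * base_guest_len))
    start, end = guest_region("A" * base_guest_len)
    reg = model_register("A" * base_guest_len)
    for i in range(start, end):
        if reg.position(i) == 0:
            seq[i] = a_letter
        elif reg.position(i) == 3:
            seq[i] = d_letter
    return "".join(seq)


ccAL = _substitute_guest_core(14, "L", "V")
ccAP = _substitute_guest_core(14, "P", "P")

PEPTIDES: dict[str, str] = {
    "RUNX2-ccd": RUNX2_CCD,
    "ccA7": ccA7,
    "ccAA": ccAA,
    "ccA21": ccA21,
    "ccQQ": ccQQ,
    "ccQ/A": ccQ_A,
    "ccA/QA": ccA_QA,
    "ccAL": ccAL,
    "ccAP": ccAP,
}
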