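"""Circular-dichroism data reduction for coiled-coil peptides.

Converts measured ellipticity (mdeg) to mean residue molar ellipticity

    [theta] = theta * mw / (10 * (n - 1) * c * pl)

with mw the peptide molecular weight (g/mol), n the number of residues
(n - 1 peptide bonds), c the concentration (mg/ml) and pl the cuvette
pathlength (cm); units deg cm^2 dmol^-1. Classifies spectra by the
222/208-nm MRE ratio (>= 1 with both minima negative is the coiled-coil
signature; a dissociated single helix gives < 1; a random coil shows a
single minimum near 200 nm with [theta]222 near zero). Normalizes
thermal melt curves to the 222-nm ellipticity at a reference
temperature (5 degC in the source experiments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TextIO

import numpy as np


class CDError(ValueError):
    """Raised for malformed CD inputs."""


@dataclass(frozen=True)
class CDMeta:
    """Metadata needed for mean-residue-ellipticity conversion."""

    mw: float  # peptide molecular weight, g/mol
    n_residues: int  # number of amino acids
    conc_mg_ml: float  # peptide concentration, mg/ml
    path_cm: float  # cuvette pathlength, cm
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise CDError("need at least 2 residues (one peptide bond)")
        if self.conc_mg_ml <= 0 or self.path_cm <= 0 or self.mw <= 0:
            raise CDError("mw, concentration and pathlength must be positive")


@dataclass(frozen=True)
class CDSpectrum:
    """Wavelength-indexed ellipticity with conversion metadata.

    ``units`` is "mdeg" for raw instrument ellipticity or "mre" after
    conversion to mean residue molar ellipticity.
    """

    wavelengths: np.ndarray  # nm, strictly increasing
    theta: np.ndarray
    meta: CDMeta
    units: str = "mdeg"

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        t = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "theta", t)
        if w.ndim != 1 or w.size != t.size:
            raise CDError("wavelengths and theta must be 1-D and equal length")
        if w.size < 2 or np.any(np.diff(w) <= 0):
            raise CDError("wavelengths must be strictly increasing (>= 2 points)")
        if w.min() < 185 or w.max() > 265:
            raise CDError("wavelengths outside the far-UV CD range (190-260 nm)")
        if self.units not in ("mdeg", "mre"):
            raise CDError(f"unknown units {self.units!r}")


@dataclass(frozen=True)
class MeltCurve:
    """222-nm ellipticity as a function of temperature."""

    temperatures: np.ndarray  # degC, increasing
    theta222: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        y = np.asarray(self.theta222, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "theta222", y)
        if t.size != y.size or t.size < 2:
            raise CDError("melt curve needs >= 2 (temperature, theta222) points")
        if np.any(np.diff(t) <= 0):
            raise CDError("temperatures must be strictly increasing")


def mean_residue_ellipticity(
    theta_mdeg: float | np.ndarray, meta: CDMeta
) -> float | np.ndarray:
    """[theta] = theta * mw / (10 * (n - 1) * c * pl), deg cm^2 dmol^-1."""
    denom = 10.0 * (meta.n_residues - 1) * meta.conc_mg_ml * meta.path_cm
    return theta_mdeg * meta.mw / denom


def to_mre(spectrum: CDSpectrum) -> CDSpectrum:
    """Convert a raw (mdeg) spectrum to mean residue ellipticity units."""
    if spectrum.units == "mre":
        return spectrum
    return replace(
        spectrum,
        theta=mean_residue_ellipticity(spectrum.theta, spectrum.meta),
        units="mre",
    )


def _value_at(spectrum: CDSpectrum, target_nm: float, tol_nm: float) -> tuple[float, bool]:
    w = spectrum.wavelengths
    if not (w.min() <= target_nm <= w.max()):
        raise CDError(f"spectrum does not span {target_nm} nm")
    nearest = float(np.min(np.abs(w - target_nm)))
    return float(np.interp(target_nm, w, spectrum.theta)), nearest > tol_nm


def ratio_222_208(
    spectrum: CDSpectrum, tol_nm: float = 1.0
) -> tuple[float, str]:
    """222/208-nm MRE ratio and its structural classification.

    Values at exactly 208 and 222 nm come from linear interpolation; a
    grid with no sample within ``tol_nm`` of either target flags the
    data as sparse. Classification: "CC-like" iff ratio >= 1 and both
    values are negative helical minima; "single-helix" (dissociated
    helices, e.g. under TFE) for negative minima with a substantial but
    sub-unity ratio; "non-helical" when the 222-nm signal is absent,
    positive, or negligible next to the ~200-nm coil minimum.
    """
    mre = to_mre(spectrum)
    v208, sparse208 = _value_at(mre, 208.0, tol_nm)
    v222, sparse222 = _value_at(mre, 222.0, tol_nm)
    sparse = " (sparse-grid)" if sparse208 or sparse222 else ""
    if v208 == 0:
        return math.nan, "undefined: [theta]208 = 0" + sparse
    ratio = v222 / v208
    if v208 < 0 and v222 < 0 and ratio >= 1.0:
        label = "CC-like"
    elif v208 < 0 and v222 < 0 and ratio >= 0.25:
        label = "single-helix"
    else:
        label = "non-helical"
    return ratio, label + sparse


def normalize_melt(curve: MeltCurve, ref_temp: float = 5.0) -> MeltCurve:
    """Divide every theta222 by the value at the point nearest ref_temp.

    The reference point maps to exactly 1.0; idempotent, and invariant
    to a global rescaling of the raw ellipticities.
    """
    idx = int(np.argmin(np.abs(curve.temperatures - ref_temp)))
    ref = curve.theta222[idx]
    if ref == 0:
        raise CDError(f"reference ellipticity at {curve.temperatures[idx]} degC is zero")
    return MeltCurve(curve.temperatures, curve.theta222 / ref, normalized=True)


# -------------------------------------------------------------------- I/O


def parse_cd_file(text: str) -> CDSpectrum:
    """Parse a two-column (wavelength_nm, theta_mdeg) table.

    Metadata comes from ``# key: value`` header lines; required keys are
    mw, n, c and pl (temperature optional), matching the quantities of
    the MRE formula.
    """
    meta_kv: dict[str, float] = {}
    rows: list[tuple[float, float]] = []
    for row_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, val = body.split(":", 1)
                try:
                    meta_kv[key.strip().lower()] = float(val)
                except ValueError:
                    pass  # free-text comment
            continue
        fields = line.replace(",", " ").split()
        if len(fields) < 2:
            raise CDError(f"row {row_no}: expected (wavelength, theta)")
        rows.append((float(fields[0]), float(fields[1])))
    missing = [k for k in ("mw", "n", "c", "pl") if k not in meta_kv]
    if missing:
        raise CDError(f"missing metadata keys: {missing}")
    if not rows:
        raise CDError("no data rows")
    rows.sort()
    w, t = zip(*rows)
    meta = CDMeta(
        mw=meta_kv["mw"], n_residues=int(meta_kv["n"]),
        conc_mg_ml=meta_kv["c"], path_cm=meta_kv["pl"],
        temperature_c=meta_kv.get("temperature", 25.0),
    )
    return CDSpectrum(np.array(w), np.array(t), meta)


def write_cd_file(spectrum: CDSpectrum, handle: TextIO | str | Path) -> None:
    m = spectrum.meta
    lines = [
        f"# mw: {m.mw}", f"# n: {m.n_residues}", f"# c: {m.conc_mg_ml}",
        f"# pl: {m.path_cm}", f"# temperature: {m.temperature_c}",
        f"# units: {spectrum.units}",
    ]
    lines += [
        f"{w:.2f}\t{t:.6g}" for w, t in zip(spectrum.wavelengths, spectrum.theta)
    ]
    text = "\n".join(lines) + "\n"
    if isinstance(handle, (str, Path)):
        Path(handle).write_text(text)
    else:
        handle.write(text)


def parse_melt_file(text: str) -> MeltCurve:
    """Parse a two-column (temperature_C, theta222_mdeg) table."""
    rows = []
    for row_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.replace(",", " ").split()
        if len(fields) < 2:
            raise CDError(f"row {row_no}: expected (temperature, theta222)")
        rows.append((float(fields[0]), float(fields[1])))
    if len(rows) < 2:
        raise CDError("melt curve needs >= 2 rows")
    rows.sort()
    t, y = zip(*rows)
    return MeltCurve(np.array(t), np.array(y))
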