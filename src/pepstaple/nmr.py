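"""Secondary chemical shifts and helix-propensity calls from assigned spectra.

The secondary shift of a residue is the observed shift minus the random-coil
reference for that residue type,

    d_delta = delta_obs - delta_RC.

Calpha nuclei move downfield (positive d_delta) in helix; Halpha nuclei move
upfield (negative).  A sustained run of like-signed secondary shifts over a
helical turn or more indicates helix propensity; isolated excursions do not.
Maleimide-linked cysteines (``C-mal``) have no published random-coil
reference, so the plain cysteine value is used — their d_delta can therefore
be out of trend and may optionally be excluded from segment calling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np

from .peptides import CANONICAL_RESIDUES

__all__ = [
    "ShiftAssignment",
    "RandomCoilTable",
    "SecondaryShiftProfile",
    "HelicalSegment",
    "NMRError",
    "load_packaged_coil_table",
    "secondary_shifts",
    "call_helical_segments",
    "classify_helix_strength",
]


class NMRError(ValueError):
    """Invalid shift table or lookup failure."""


@dataclass(frozen=True)
class ShiftAssignment:
    """Assigned shifts for one residue (parent numbering); ppm, DSS-referenced."""

    residue_index: int
    residue_type: str
    delta_ca: Optional[float] = None
    delta_ha: Optional[float] = None
    peak_width: Optional[float] = None

    def __post_init__(self) -> None:
        if self.delta_ca is None and self.delta_ha is None:
            raise NMRError(
                f"residue {self.residue_index}: at least one of delta_ca/delta_ha required"
            )


@dataclass
class RandomCoilTable:
    """Residue-type -> (coil Calpha, coil Halpha) reference shifts in ppm.

    ``C-mal`` (maleimide-linked cysteine) resolves to the plain Cys entry.
    """

    shifts: dict[str, tuple[Optional[float], Optional[float]]]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = CANONICAL_RESIDUES - set(self.shifts)
        if missing:
            raise NMRError(f"random-coil table missing residues: {sorted(missing)}")

    def lookup(self, residue_type: str) -> tuple[Optional[float], Optional[float]]:
        key = "C" if residue_type == "C-mal" else residue_type
        try:
            return self.shifts[key]
        except KeyError:
            raise NMRError(f"no random-coil reference for residue type {residue_type!r}") from None


@dataclass
class HelicalSegment:
    """A maximal run of helix-sense secondary shifts, parent numbering, inclusive."""

    start: int
    end: int
    sense: str  # "ca-downfield" | "ha-upfield"


@dataclass
class SecondaryShiftProfile:
    """Per-residue secondary shifts; NaN where a nucleus is unassigned."""

    residue_index: np.ndarray
    residue_type: list[str]
    d_delta_ca: np.ndarray
    d_delta_ha: np.ndarray
    uncertainty: np.ndarray
    segments: list[HelicalSegment] = field(default_factory=list)


def load_packaged_coil_table() -> RandomCoilTable:
    """The approximate consensus table shipped with the package (see its header)."""
    shifts: dict[str, tuple[Optional[float], Optional[float]]] = {}
    text = resources.files("pepstaple").joinpath("data/random_coil_shifts.tsv").read_text()
    for row in csv.reader(
        (line for line in text.splitlines() if line.strip() and not line.startswith("#")),
        delimiter="\t",
    ):
        shifts[row[0]] = (float(row[1]), float(row[2]))
    return RandomCoilTable(
        shifts=shifts,
        provenance="packaged approximate consensus random-coil values; see data file header",
    )


def secondary_shifts(
    assignments: Sequence[ShiftAssignment], table: RandomCoilTable
) -> SecondaryShiftProfile:
    """d_delta = delta_obs - delta_RC per residue and nucleus.

    Missing nuclei propagate as NaN; duplicate residue indices are rejected.
    """
    if not assignments:
        raise NMRError("empty assignment list")
    ordered = sorted(assignments, key=lambda a: a.residue_index)
    idx = [a.residue_index for a in ordered]
    if len(set(idx)) != len(idx):
        raise NMRError("duplicate residue_index in assignment table")
    dca, dha, unc, types = [], [], [], []
    for a in ordered:
        rc_ca, rc_ha = table.lookup(a.residue_type)
        dca.append(a.delta_ca - rc_ca if a.delta_ca is not None and rc_ca is not None else np.nan)
        dha.append(a.delta_ha - rc_ha if a.delta_ha is not None and rc_ha is not None else np.nan)
        unc.append(a.peak_width if a.peak_width is not None else np.nan)
        types.append(a.residue_type)
    return SecondaryShiftProfile(
        residue_index=np.array(idx, dtype=int),
        residue_type=types,
        d_delta_ca=np.array(dca, dtype=float),
        d_delta_ha=np.array(dha, dtype=float),
        uncertainty=np.array(unc, dtype=float),
    )


def call_helical_segments(
    profile: SecondaryShiftProfile,
    min_run: int = 4,
    ca_threshold: float = 0.1,
    nucleus: str = "ca",
    exclude_cmal: bool = False,
) -> list[HelicalSegment]:
    """Maximal runs of >= min_run consecutive residues in helix sense.

    Helix sense is d_delta_Ca > threshold (downfield) or, in Halpha mode,
    d_delta_Ha < -threshold (upfield).  Runs must be consecutive in parent
    numbering — a gap in the assignment breaks a run.  ``exclude_cmal``
    makes maleimide-cysteine residues ineligible (their coil reference is a
    stand-in), without masking their d_delta in the profile itself.
    """
    if nucleus not in ("ca", "ha"):
        raise NMRError(f"nucleus must be 'ca' or 'ha', got {nucleus!r}")
    if nucleus == "ca":
        values = profile.d_delta_ca
        passes = values > ca_threshold
        sense = "ca-downfield"
    else:
        values = profile.d_delta_ha
        passes = values < -ca_threshold
        sense = "ha-upfield"
    passes = passes & ~np.isnan(values)
    if exclude_cmal:
        passes = passes & np.array([t != "C-mal" for t in profile.residue_type])

    segments: list[HelicalSegment] = []
    idx = profile.residue_index
    run_start: Optional[int] = None
    prev_i: Optional[int] = None
    for k in range(len(idx)):
        contiguous = prev_i is not None and idx[k] == prev_i + 1
        if passes[k]:
            if run_start is None or not contiguous:
                if run_start is not None and prev_i - run_start + 1 >= min_run:
                    segments.append(HelicalSegment(int(run_start), int(prev_i), sense))
                run_start = idx[k]
        else:
            if run_start is not None and prev_i - run_start + 1 >= min_run:
                segments.append(HelicalSegment(int(run_start), int(prev_i), sense))
            run_start = None
        prev_i = idx[k]
    if run_start is not None and prev_i - run_start + 1 >= min_run:
        segments.append(HelicalSegment(int(run_start), int(prev_i), sense))
    return segments


#: d_delta_Ca band edges (ppm): below 0.1 is within coil noise; heavily
#: stabilised helices run to >= 2.0-3.5 downfield.
COIL_BAND = 0.1
STRONG_BAND = 2.0


def classify_helix_strength(profile: SecondaryShiftProfile) -> list[str]:
    """Per-residue label from d_delta_Ca: coil-like / weak-helical / strong-helical.

    Only downfield (positive) shifts count toward helix; upfield excursions
    — e.g. at constrained cysteines — stay coil-like.  NaN yields
    "unassigned".
    """
    labels = []
    for v in profile.d_delta_ca:
        if np.isnan(v):
            labels.append("unassigned")
        elif v >= STRONG_BAND:
            labels.append("strong-helical")
        elif v >= COIL_BAND:
            labels.append("weak-helical")
        else:
            labels.append("coil-like")
    return labels
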