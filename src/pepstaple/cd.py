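"""Circular dichroism: mean residue ellipticity and helicity estimation.

Raw ellipticity (mdeg) is blank-subtracted and normalised to mean residue
ellipticity

    MRE(lambda) = (theta_lambda - theta_0) * Mw / (n_res * l * c)

with Mw in g/mol, pathlength l in mm and concentration c in mg/mL (the mm
convention absorbs the usual factor of 10).  Fractional helix content is
estimated from MRE at 222 nm against coil and full-helix limits:

    % helicity = (MRE_222 - MRE_coil) * 100 / (-42500 * (1 - 3/n))

where MRE_coil = 640 - 45*T (T in deg C) and n is the number of backbone
amide bonds including the terminal caps — note this n differs from the
residue count used in the MRE normalisation, and the two are deliberately
kept as separate metadata fields.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CDSpectrum",
    "MRESpectrum",
    "HelicityEstimate",
    "CDError",
    "zero_blank",
    "mre_spectrum",
    "mre_at",
    "coil_baseline",
    "percent_helicity",
    "helicity_from_spectrum",
    "average_duplicate_spectra",
]

FULL_HELIX_MRE = -42500.0  # deg cm^2 dmol^-1 res^-1, infinite-helix limit at 222 nm


class CDError(ValueError):
    """Invalid CD spectrum or operation."""


@dataclass
class CDSpectrum:
    """A raw CD spectrum in mdeg with the sample metadata needed for MRE."""

    wavelengths: np.ndarray  # nm, strictly monotone grid
    ellipticity_mdeg: np.ndarray
    mw: Optional[float] = None  # g/mol
    conc_mg_ml: Optional[float] = None
    pathlength_mm: float = 1.0
    n_residues: Optional[int] = None
    n_amide: Optional[int] = None
    temperature_c: float = 5.0
    is_blank: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity_mdeg = np.asarray(self.ellipticity_mdeg, dtype=float)
        if self.wavelengths.size != self.ellipticity_mdeg.size:
            raise CDError("wavelength and ellipticity arrays differ in length")
        if self.wavelengths.size < 2:
            raise CDError("spectrum needs at least 2 points")
        d = np.diff(self.wavelengths)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise CDError("wavelength grid must be strictly monotone")
        if not self.is_blank:
            if self.conc_mg_ml is not None and self.conc_mg_ml <= 0:
                raise CDError(f"concentration must be > 0, got {self.conc_mg_ml}")
            if self.pathlength_mm <= 0:
                raise CDError(f"pathlength must be > 0, got {self.pathlength_mm}")


@dataclass
class MRESpectrum:
    """Mean-residue-ellipticity spectrum (deg cm^2 dmol^-1 res^-1)."""

    wavelengths: np.ndarray
    mre: np.ndarray
    name: str = ""


@dataclass(frozen=True)
class HelicityEstimate:
    """MRE at 222 nm, coil baseline, and the helicity estimate it implies."""

    mre222: float
    mre_coil: float
    percent_helicity: float
    rounded_percent: int


def zero_blank(wavelengths: np.ndarray) -> CDSpectrum:
    """An explicit all-zero blank on the given grid (no-buffer-signal case)."""
    wl = np.asarray(wavelengths, dtype=float)
    return CDSpectrum(wavelengths=wl, ellipticity_mdeg=np.zeros_like(wl),
                      is_blank=True, name="zero-blank")


def mre_spectrum(sample: CDSpectrum, blank: CDSpectrum, interpolate: bool = False) -> MRESpectrum:
    """Blank-subtract and normalise a raw spectrum to MRE.

    The blank must share the sample grid, or ``interpolate`` must be set to
    resample it linearly (its grid must then cover the sample's).
    """
    for attr, label in ((sample.mw, "Mw"), (sample.conc_mg_ml, "concentration"),
                        (sample.n_residues, "n_residues")):
        if attr is None:
            raise CDError(f"sample metadata missing {label}, required for MRE")
    if np.array_equal(sample.wavelengths, blank.wavelengths):
        theta0 = blank.ellipticity_mdeg
    elif interpolate:
        lo, hi = blank.wavelengths.min(), blank.wavelengths.max()
        if sample.wavelengths.min() < lo or sample.wavelengths.max() > hi:
            raise CDError("blank grid does not cover the sample grid")
        order = np.argsort(blank.wavelengths)
        theta0 = np.interp(sample.wavelengths, blank.wavelengths[order],
                           blank.ellipticity_mdeg[order])
    else:
        raise CDError("sample and blank wavelength grids differ (pass interpolate=True)")
    mre = (sample.ellipticity_mdeg - theta0) * sample.mw / (
        sample.n_residues * sample.pathlength_mm * sample.conc_mg_ml
    )
    return MRESpectrum(wavelengths=sample.wavelengths.copy(), mre=mre, name=sample.name)


def mre_at(spectrum: MRESpectrum, wavelength: float = 222.0) -> float:
    """MRE at the grid point nearest the requested wavelength (1 nm grids)."""
    wl = spectrum.wavelengths
    if wavelength < wl.min() or wavelength > wl.max():
        raise CDError(f"wavelength {wavelength} nm outside spectrum span "
                      f"[{wl.min()}, {wl.max()}]")
    return float(spectrum.mre[int(np.argmin(np.abs(wl - wavelength)))])


def coil_baseline(temperature_c: float) -> float:
    """Random-coil MRE at 222 nm: 640 - 45*T (T in deg C)."""
    return 640.0 - 45.0 * temperature_c


def percent_helicity(mre222: float, n_amide: int, temperature_c: float) -> HelicityEstimate:
    """Fractional helicity from MRE at 222 nm.

    ``n_amide`` is the number of backbone amide bonds including the terminal
    caps (residues + 1 for an Ac/NH2 peptide); the 1 - 3/n factor corrects
    the infinite-helix limit for finite chain length.
    """
    if n_amide <= 3:
        raise CDError(f"n_amide must exceed 3 for the chain-length correction, got {n_amide}")
    coil = coil_baseline(temperature_c)
    pct = (mre222 - coil) * 100.0 / (FULL_HELIX_MRE * (1.0 - 3.0 / n_amide))
    return HelicityEstimate(
        mre222=mre222,
        mre_coil=coil,
        percent_helicity=pct,
        rounded_percent=int(round(pct)),
    )


def helicity_from_spectrum(sample: CDSpectrum, blank: Optional[CDSpectrum] = None,
                           wavelength: float = 222.0) -> HelicityEstimate:
    """Full pipeline: blank-subtract, normalise, read 222 nm, estimate helicity."""
    if sample.n_amide is None:
        raise CDError("sample metadata missing n_amide, required for helicity")
    if blank is None:
        blank = zero_blank(sample.wavelengths)
    spec = mre_spectrum(sample, blank)
    return percent_helicity(mre_at(spec, wavelength), sample.n_amide, sample.temperature_c)


def average_duplicate_spectra(spectra: Sequence[CDSpectrum]) -> CDSpectrum:
    """Pointwise mean of replicate spectra sharing grid and metadata."""
    if not spectra:
        raise CDError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, first.wavelengths):
            raise CDError("replicate spectra must share a wavelength grid")
        meta = ("mw", "conc_mg_ml", "pathlength_mm", "n_residues", "n_amide",
                "temperature_c", "is_blank")
        for m in meta:
            if getattr(s, m) != getattr(first, m):
                raise CDError(f"replicate spectra disagree on metadata field {m!r}")
    mean = np.mean([s.ellipticity_mdeg for s in spectra], axis=0)
    return replace(first, ellipticity_mdeg=mean)
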