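"""Synthetic data generators with known ground truth for every pipeline stage.

These emulate the assay conditions of the competition fluorescence-anisotropy
screen (50 nM fluorescein-labelled tracer, 15 uM protein, triplicate wells,
Gaussian anisotropy read noise), CD spectra of helix/coil mixtures whose
222 nm value inverts the helicity formula exactly, and per-residue secondary
shift profiles of a partially helical peptide.  Every generator is a pure
function of its parameters and the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .anisotropy import (
    TitrationSeries,
    anisotropy_from_bound_fraction,
    logistic_curve,
    quadratic_bound_fraction,
)
from .cd import CDSpectrum, coil_baseline, FULL_HELIX_MRE
from .nmr import RandomCoilTable, ShiftAssignment
from .peptides import CANONICAL_RESIDUES, PeptideSpec

__all__ = [
    "SimulationConfig",
    "default_x_grid",
    "simulate_direct_titration",
    "simulate_competition_logistic",
    "simulate_competition_equilibrium",
    "solve_competition_equilibrium",
    "half_displacement_concentration",
    "simulate_cd_spectrum",
    "make_synthetic_coil_table",
    "simulate_shift_profile",
    "SimulatedShiftProfile",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Assay constants and noise model shared by the generators.

    Defaults mirror the screen's conditions: 50 nM tracer, 15 uM protein,
    triplicate reads, 0.003 anisotropy-unit Gaussian noise, 25 C.
    """

    seed: int = 0
    noise_sd_anisotropy: float = 0.003
    replicates: int = 3
    x_grid: Optional[np.ndarray] = None
    tracer_conc: float = 50e-9
    protein_conc: float = 15e-6
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        if self.noise_sd_anisotropy < 0:
            raise ValueError("noise SD must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_x_grid(midpoint: float, n_points: int = 12) -> np.ndarray:
    """12 log-spaced concentrations spanning 0.01-100x the curve midpoint."""
    return np.logspace(math.log10(midpoint) - 2, math.log10(midpoint) + 2, n_points)


def _noisy_replicates(y: np.ndarray, config: SimulationConfig) -> list[list[float]]:
    rng = config.rng()
    reads = []
    for yi in y:
        reads.append(list(yi + rng.normal(0.0, config.noise_sd_anisotropy,
                                          config.replicates))
                     if config.noise_sd_anisotropy > 0
                     else [float(yi)] * config.replicates)
    return reads


def simulate_direct_titration(
    Kd: float,
    r_min: float = 0.05,
    r_max: float = 0.25,
    lam: float = 1.0,
    config: SimulationConfig = SimulationConfig(),
) -> TitrationSeries:
    """Saturation curve of tracer anisotropy vs added protein.

    Bound fraction follows the tight-binding quadratic at the configured
    tracer concentration; anisotropy interpolates between r_min and r_max.
    """
    if Kd <= 0:
        raise ValueError(f"Kd must be positive, got {Kd}")
    x = config.x_grid if config.x_grid is not None else default_x_grid(Kd)
    x = np.asarray(x, dtype=float)
    lb = quadratic_bound_fraction(x, Kd, config.tracer_conc)
    y = anisotropy_from_bound_fraction(lb, r_min, r_max, lam)
    return TitrationSeries(
        mode="direct",
        x=x,
        reads=_noisy_replicates(y, config),
        tracer_conc=config.tracer_conc,
        ground_truth={"Kd": Kd, "r_min": r_min, "r_max": r_max, "lambda": lam},
    )


def simulate_competition_logistic(
    IC50: float,
    p: float = 1.2,
    r_min: float = -0.03,
    r_max: float = 0.12,
    config: SimulationConfig = SimulationConfig(),
) -> TitrationSeries:
    """Phenomenological 4PL displacement curve, high anisotropy to low."""
    if IC50 <= 0:
        raise ValueError(f"IC50 must be positive, got {IC50}")
    x = config.x_grid if config.x_grid is not None else default_x_grid(IC50)
    x = np.asarray(x, dtype=float)
    y = logistic_curve(x, IC50, p, r_min, r_max)
    return TitrationSeries(
        mode="competition",
        x=x,
        reads=_noisy_replicates(y, config),
        tracer_conc=config.tracer_conc,
        protein_conc=config.protein_conc,
        ground_truth={"IC50": IC50, "p": p, "r_min": r_min, "r_max": r_max},
    )


# -- exact competitive-equilibrium oracle ---------------------------------


def solve_competition_equilibrium(
    protein_total: float,
    tracer_total: float,
    competitor_total: float,
    Kd_tracer: float,
    Kd_competitor: float,
) -> dict[str, float]:
    """Exact species concentrations for two ligands competing for one site.

    Solves the protein mass balance
        p + p*T/(Kd_T + p) + p*C/(Kd_C + p) = P_total
    for free protein p (monotone in p, bracketed by [0, P_total]) to machine
    precision, then back-substitutes all species.
    """
    if Kd_tracer <= 0 or Kd_competitor <= 0:
        raise ValueError("dissociation constants must be positive")
    if min(protein_total, tracer_total, competitor_total) < 0:
        raise ValueError("totals must be non-negative")

    def balance(p: float) -> float:
        return (p
                + p * tracer_total / (Kd_tracer + p)
                + p * competitor_total / (Kd_competitor + p)
                - protein_total)

    if protein_total == 0:
        p_free = 0.0
    else:
        p_free = brentq(balance, 0.0, protein_total, xtol=1e-300, rtol=8.9e-16,
                        maxiter=200)
    tracer_bound = p_free * tracer_total / (Kd_tracer + p_free)
    comp_bound = p_free * competitor_total / (Kd_competitor + p_free)
    return {
        "protein_free": p_free,
        "tracer_bound": tracer_bound,
        "tracer_free": tracer_total - tracer_bound,
        "competitor_bound": comp_bound,
        "competitor_free": competitor_total - comp_bound,
        "tracer_bound_fraction": tracer_bound / tracer_total if tracer_total > 0 else 0.0,
    }


def half_displacement_concentration(
    Kd_tracer: float,
    Kd_competitor: float,
    protein_total: float,
    tracer_total: float,
    bracket: tuple[float, float] = (1e-15, 10.0),
) -> float:
    """Competitor concentration halving the no-competitor tracer bound fraction.

    Found by bisection on the exact equilibrium — the thermodynamic IC50
    against which logistic fits can be benchmarked.
    """
    lb0 = solve_competition_equilibrium(
        protein_total, tracer_total, 0.0, Kd_tracer, Kd_competitor
    )["tracer_bound_fraction"]
    target = lb0 / 2.0

    def gap(log_c: float) -> float:
        lb = solve_competition_equilibrium(
            protein_total, tracer_total, math.exp(log_c), Kd_tracer, Kd_competitor
        )["tracer_bound_fraction"]
        return lb - target

    lo, hi = math.log(bracket[0]), math.log(bracket[1])
    return math.exp(brentq(gap, lo, hi, xtol=1e-13, maxiter=200))


def simulate_competition_equilibrium(
    Kd_tracer: float,
    Kd_competitor: float,
    r_min: float = -0.03,
    r_max: float = 0.12,
    config: SimulationConfig = SimulationConfig(),
) -> TitrationSeries:
    """Displacement curve from exact competitive thermodynamics.

    Anisotropy maps linearly (lambda = 1) from the tracer bound fraction
    scaled to its no-competitor value; ground truth records the bisection
    half-displacement concentration.
    """
    try:
        half = half_displacement_concentration(
            Kd_tracer, Kd_competitor, config.protein_conc, config.tracer_conc
        )
    except ValueError:
        half = None  # competitor too weak to reach half-displacement in bracket
    if config.x_grid is not None:
        x = config.x_grid
    elif half is not None:
        x = default_x_grid(half)
    else:
        raise ValueError("competitor never reaches half-displacement; supply x_grid")
    x = np.asarray(x, dtype=float)
    lb0 = solve_competition_equilibrium(
        config.protein_conc, config.tracer_conc, 0.0, Kd_tracer, Kd_competitor
    )["tracer_bound_fraction"]
    lbs = np.array([
        solve_competition_equilibrium(
            config.protein_conc, config.tracer_conc, xi, Kd_tracer, Kd_competitor
        )["tracer_bound_fraction"]
        for xi in x
    ])
    # r_max corresponds to the undisplaced (zero-competitor) bound level
    y = anisotropy_from_bound_fraction(lbs / lb0, r_min, r_max, 1.0)
    return TitrationSeries(
        mode="competition",
        x=x,
        reads=_noisy_replicates(y, config),
        tracer_conc=config.tracer_conc,
        protein_conc=config.protein_conc,
        ground_truth={
            "Kd_tracer": Kd_tracer,
            "Kd_competitor": Kd_competitor,
            "half_displacement": half,
            "r_min": r_min,
            "r_max": r_max,
        },
    )


# -- CD -------------------------------------------------------------------


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((wl - center) / width) ** 2))


def _helix_shape(wl: np.ndarray) -> np.ndarray:
    # double minimum at 208/222 nm, strong positive band at ~192 nm
    return (-39000.0 * (_gauss(wl, 222.0, 6.5) + _gauss(wl, 208.0, 6.0))
            + 60000.0 * _gauss(wl, 192.0, 6.0))


def _coil_shape(wl: np.ndarray) -> np.ndarray:
    # deep minimum near 198 nm, weak positive shoulder above 215 nm
    return -20000.0 * _gauss(wl, 198.0, 8.0) + 1500.0 * _gauss(wl, 220.0, 25.0)


def simulate_cd_spectrum(
    true_helicity: float,
    n_amide: int,
    temperature_c: float = 5.0,
    config: SimulationConfig = SimulationConfig(),
    mw: float = 2540.0,
    conc_mg_ml: float = 0.1,
    pathlength_mm: float = 1.0,
    noise_sd_mdeg: float = 0.0,
    wavelengths: Optional[np.ndarray] = None,
) -> CDSpectrum:
    """Raw-mdeg spectrum of a helix/coil mixture with exactly known helicity.

    The two basis shapes are smooth helix- and coil-like curves whose 222 nm
    values are pinned so that the MRE -> helicity formula applied to the
    noiseless spectrum (with a zero blank) returns ``true_helicity`` exactly
    for the given n_amide and temperature; away from 222 nm the shapes are
    only cosmetically realistic.
    """
    if not (0.0 <= true_helicity <= 100.0):
        raise ValueError(f"true_helicity must be in [0, 100], got {true_helicity}")
    wl = (np.arange(190.0, 261.0) if wavelengths is None
          else np.asarray(wavelengths, dtype=float))
    n_res = n_amide - 1  # Ac/NH2 convention
    coil222_target = coil_baseline(temperature_c)
    helix222_target = coil222_target + FULL_HELIX_MRE * (1.0 - 3.0 / n_amide)
    coil = _coil_shape(wl) * (coil222_target / float(_coil_shape(np.array([222.0]))[0]))
    helix = _helix_shape(wl) * (helix222_target / float(_helix_shape(np.array([222.0]))[0]))
    h = true_helicity / 100.0
    mre = h * helix + (1.0 - h) * coil
    theta = mre * n_res * pathlength_mm * conc_mg_ml / mw
    if noise_sd_mdeg > 0:
        theta = theta + config.rng().normal(0.0, noise_sd_mdeg, wl.size)
    return CDSpectrum(
        wavelengths=wl,
        ellipticity_mdeg=theta,
        mw=mw,
        conc_mg_ml=conc_mg_ml,
        pathlength_mm=pathlength_mm,
        n_residues=n_res,
        n_amide=n_amide,
        temperature_c=temperature_c,
        name=f"synthetic h={true_helicity}%",
    )


# -- NMR ------------------------------------------------------------------


def make_synthetic_coil_table(seed: int = 0) -> RandomCoilTable:
    """A synthetic random-coil table (all 20 residues + pS), seeded.

    Values are arbitrary but deterministic; quantitative round-trip tests
    use this so that nothing depends on literature reference values.
    """
    rng = np.random.default_rng(seed)
    shifts = {}
    for res in sorted(CANONICAL_RESIDUES) + ["pS"]:
        shifts[res] = (float(50.0 + rng.uniform(-5, 15)), float(4.4 + rng.uniform(-0.5, 0.5)))
    return RandomCoilTable(shifts=shifts, provenance=f"synthetic, seed={seed}")


@dataclass
class SimulatedShiftProfile:
    """Assignments plus the table and truth they were generated from."""

    assignments: list[ShiftAssignment]
    coil_table: RandomCoilTable
    true_d_delta_ca: np.ndarray
    true_d_delta_ha: np.ndarray


def simulate_shift_profile(
    sequence: Union[str, Sequence[str], PeptideSpec],
    per_residue_helix_fraction: Sequence[float],
    amplitude_ca: float = 3.0,
    amplitude_ha: float = -0.35,
    offset: int = 1,
    coil_table: Optional[RandomCoilTable] = None,
    noise_sd_ppm: float = 0.0,
    config: SimulationConfig = SimulationConfig(),
) -> SimulatedShiftProfile:
    """Per-residue shifts delta_RC + f_i * amplitude (+ noise).

    ``amplitude_ca`` is the full-helix downfield Calpha displacement
    (~3 ppm); ``amplitude_ha`` the full-helix upfield Halpha displacement
    (negative).  Fractions are per-residue helix populations in [0, 1].
    """
    if isinstance(sequence, PeptideSpec):
        residues = list(sequence.residues)
        offset = sequence.numbering_offset
    elif isinstance(sequence, str):
        from .peptides import parse_peptide

        residues = list(parse_peptide(sequence, offset).residues)
    else:
        residues = list(sequence)
    f = np.asarray(per_residue_helix_fraction, dtype=float)
    if f.size != len(residues):
        raise ValueError(f"{len(residues)} residues but {f.size} helix fractions")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("helix fractions must lie in [0, 1]")
    table = coil_table if coil_table is not None else make_synthetic_coil_table(config.seed)
    rng = config.rng()
    true_ca = f * amplitude_ca
    true_ha = f * amplitude_ha
    noise_ca = rng.normal(0.0, noise_sd_ppm, f.size) if noise_sd_ppm > 0 else np.zeros(f.size)
    noise_ha = rng.normal(0.0, noise_sd_ppm, f.size) if noise_sd_ppm > 0 else np.zeros(f.size)
    assignments = []
    for k, res in enumerate(residues):
        rc_ca, rc_ha = table.lookup(res)
        assignments.append(ShiftAssignment(
            residue_index=offset + k,
            residue_type=res,
            delta_ca=rc_ca + true_ca[k] + noise_ca[k],
            delta_ha=rc_ha + true_ha[k] + noise_ha[k],
        ))
    return SimulatedShiftProfile(
        assignments=assignments,
        coil_table=table,
        true_d_delta_ca=true_ca,
        true_d_delta_ha=true_ha,
    )
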