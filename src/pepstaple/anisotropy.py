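"""Fluorescence-anisotropy processing and binding/competition fitting.

A plate reader measures parallel (S) and perpendicular (P) emission
intensities; with the instrument G factor these give total intensity

    I = 2*P*G + S

and anisotropy

    r = (S - G*P) / (S + 2*G*P)

Direct titrations (protein titrated into a fixed tracer concentration) are
fitted with the tight-binding (Morrison) quadratic for the tracer bound
fraction

    L_b(x) = ((x + FL + Kd) - sqrt((x + FL + Kd)^2 - 4*x*FL)) / (2*FL)

which accounts for ligand depletion when the tracer concentration [FL] is
not negligible against Kd.  Anisotropy relates to bound fraction through

    L_b = (r - r_min) / (lambda*(r_max - r) + r - r_min)

with lambda the bound/free intensity-change factor (1 for this assay).

Competition (displacement) titrations are fitted with a four-parameter
logistic in competitor concentration x; the IC50 is the logistic midpoint
x0.  Potency differences convert to free energy via dG = -R*T*ln(fold).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import lmfit

__all__ = [
    "GAS_CONSTANT_J",
    "AnisotropyRead",
    "TitrationSeries",
    "DirectFitResult",
    "CompetitionFitResult",
    "AnisotropyError",
    "FitError",
    "total_intensity",
    "anisotropy",
    "bound_fraction",
    "anisotropy_from_bound_fraction",
    "quadratic_bound_fraction",
    "logistic_curve",
    "fit_direct_titration",
    "fit_competition",
    "delta_delta_g",
    "aggregate_replicates",
]

GAS_CONSTANT_J = 8.314  # J mol^-1 K^-1


class AnisotropyError(ValueError):
    """Invalid anisotropy data or computation."""


class FitError(RuntimeError):
    """Nonlinear fit failed; carries the best parameters found, if any."""

    def __init__(self, message: str, best: Optional[dict] = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class AnisotropyRead:
    """One well's polarized intensities: perpendicular P, parallel S, G factor."""

    P: float
    S: float
    G: float = 1.0

    def __post_init__(self) -> None:
        if self.P < 0 or self.S < 0:
            raise AnisotropyError(f"intensities must be non-negative, got P={self.P}, S={self.S}")
        if self.G <= 0:
            raise AnisotropyError(f"G factor must be positive, got {self.G}")


Read = Union[AnisotropyRead, float]


@dataclass
class TitrationSeries:
    """Concentration series with replicate anisotropy observations.

    ``x`` is added protein concentration (direct mode) or added competitor
    concentration (competition mode), in molar, strictly positive and
    ascending.  ``reads`` holds, per x, replicate raw reads or precomputed
    anisotropy values.  ``ground_truth`` is attached by the simulators.
    """

    mode: str  # "direct" | "competition"
    x: np.ndarray
    reads: list[list[Read]]
    tracer_conc: float = 50e-9
    protein_conc: Optional[float] = None
    temperature: float = 298.15
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "competition"):
            raise AnisotropyError(f"mode must be 'direct' or 'competition', got {self.mode!r}")
        self.x = np.asarray(self.x, dtype=float)
        if self.x.size < 2 or np.unique(self.x).size < 2:
            raise AnisotropyError("need at least 2 distinct concentrations")
        if np.any(self.x <= 0):
            raise AnisotropyError("concentrations must be strictly positive")
        if np.any(np.diff(self.x) < 0):
            raise AnisotropyError("concentrations must be sorted ascending")
        if len(self.reads) != self.x.size:
            raise AnisotropyError("reads must have one replicate list per concentration")
        if any(len(r) < 1 for r in self.reads):
            raise AnisotropyError("every concentration needs at least one replicate")

    def anisotropies(self) -> list[np.ndarray]:
        """Per-x replicate anisotropy values (raw reads converted on the fly)."""
        out = []
        for reps in self.reads:
            out.append(np.array([
                anisotropy(r) if isinstance(r, AnisotropyRead) else float(r)
                for r in reps
            ]))
        return out

    @property
    def n_replicates(self) -> int:
        return max(len(r) for r in self.reads)


@dataclass
class DirectFitResult:
    """Tight-binding quadratic fit of a direct titration."""

    Kd: float
    r_min: float
    r_max: float
    lam: float
    Kd_stderr: Optional[float]
    r_min_stderr: Optional[float]
    r_max_stderr: Optional[float]
    residual_sum: float
    converged: bool

    def predict(self, x: np.ndarray, tracer_conc: float) -> np.ndarray:
        lb = quadratic_bound_fraction(np.asarray(x, float), self.Kd, tracer_conc)
        return anisotropy_from_bound_fraction(lb, self.r_min, self.r_max, self.lam)


@dataclass
class CompetitionFitResult:
    """Four-parameter logistic fit of a competition titration."""

    IC50: float
    hill: float
    r_min: float
    r_max: float
    restrained_rmin: bool
    IC50_sd: Optional[float]
    IC50_stderr: Optional[float]
    residual_sum: float
    converged: bool
    monotonicity_warning: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        return logistic_curve(np.asarray(x, float), self.IC50, self.hill, self.r_min, self.r_max)


# -- elementary observables ----------------------------------------------


def total_intensity(read: AnisotropyRead) -> float:
    """Total fluorescence intensity I = 2*P*G + S."""
    return 2.0 * read.P * read.G + read.S


def anisotropy(read: AnisotropyRead) -> float:
    """Anisotropy r = (S - G*P) / (S + 2*G*P); always in [-0.5, 1].

    The bounds are attained only at the degenerate channel readings S = 0
    (r = -0.5) and P = 0 (r = 1); any mixed signal lies strictly inside.
    """
    denom = read.S + 2.0 * read.G * read.P
    if denom <= 0:
        raise AnisotropyError("anisotropy undefined: total intensity is zero")
    return (read.S - read.G * read.P) / denom


def bound_fraction(
    r: float,
    r_min: float,
    r_max: float,
    lam: float = 1.0,
    overshoot_tol: float = 0.05,
) -> float:
    """Tracer bound fraction from anisotropy.

    L_b = (r - r_min) / (lam*(r_max - r) + r - r_min), clamped to [0, 1].
    Noise can push r slightly past the asymptotes; overshoot beyond
    ``overshoot_tol`` (as a fraction of the window) triggers a warning but
    is still clamped.
    """
    if r_max <= r_min:
        raise AnisotropyError(f"degenerate anisotropy window: r_max={r_max} <= r_min={r_min}")
    window = r_max - r_min
    over = max(r_min - r, r - r_max) / window
    if over > overshoot_tol:
        warnings.warn(
            f"anisotropy {r} overshoots window [{r_min}, {r_max}] by {over:.1%}",
            stacklevel=2,
        )
    r = min(max(r, r_min), r_max)
    denom = lam * (r_max - r) + (r - r_min)
    if denom == 0:
        return 1.0
    return min(max((r - r_min) / denom, 0.0), 1.0)


def anisotropy_from_bound_fraction(
    lb: np.ndarray, r_min: float, r_max: float, lam: float = 1.0
) -> np.ndarray:
    """Inverse of :func:`bound_fraction`; linear mixing when lam == 1."""
    lb = np.asarray(lb, dtype=float)
    return (lam * lb * r_max + (1.0 - lb) * r_min) / (1.0 - lb + lam * lb)


def quadratic_bound_fraction(x, Kd: float, tracer_conc: float):
    """Morrison tight-binding bound fraction of the tracer.

    Evaluated in the conjugate form L_b = 2x / (b + sqrt(b^2 - 4*x*FL)) with
    b = x + FL + Kd, which is numerically stable as FL -> 0 (where it
    collapses to the hyperbolic isotherm x/(x+Kd)).
    """
    if Kd <= 0:
        raise AnisotropyError(f"Kd must be positive, got {Kd}")
    if tracer_conc < 0:
        raise AnisotropyError(f"tracer concentration must be non-negative, got {tracer_conc}")
    x = np.asarray(x, dtype=float)
    b = x + tracer_conc + Kd
    disc = np.sqrt(np.maximum(b * b - 4.0 * x * tracer_conc, 0.0))
    return 2.0 * x / (b + disc)


def logistic_curve(x, x0: float, p: float, low: float, high: float):
    """4PL oriented high -> low: y(0) = high, y(inf) = low, midpoint at x0."""
    x = np.asarray(x, dtype=float)
    return low + (high - low) / (1.0 + (x / x0) ** p)


# -- aggregation ----------------------------------------------------------


def aggregate_replicates(series: TitrationSeries) -> pd.DataFrame:
    """Per-concentration mean and sample SD of replicate anisotropies.

    SD is 0 where only a single replicate exists.
    """
    rows = []
    for xi, reps in zip(series.x, series.anisotropies()):
        # identical replicates get an exact 0, not mean-roundoff noise
        if reps.size == 1 or np.all(reps == reps[0]):
            sd = 0.0
        else:
            sd = float(np.std(reps, ddof=1))
        rows.append({"x": float(xi), "mean": float(np.mean(reps)), "sd": sd, "n": reps.size})
    return pd.DataFrame(rows)


# -- fitting --------------------------------------------------------------


def _check_converged(result: lmfit.minimizer.MinimizerResult, label: str) -> None:
    if not result.success:
        best = {k: v.value for k, v in result.params.items()}
        raise FitError(f"{label} fit did not converge: {result.message}", best=best)


def fit_direct_titration(
    series: TitrationSeries,
    fix_lambda: bool = True,
    lam: float = 1.0,
    weighted: bool = False,
) -> DirectFitResult:
    """Fit Kd, r_min, r_max (and optionally lambda) to a direct titration.

    Unweighted least squares on per-x replicate means by default, matching
    how plate-reader titrations are usually analysed; ``weighted`` divides
    residuals by replicate SD where available.
    """
    if series.mode != "direct":
        raise AnisotropyError("fit_direct_titration requires a direct-mode series")
    if series.tracer_conc <= 0:
        raise AnisotropyError("direct fit requires tracer_conc > 0")
    agg = aggregate_replicates(series)
    x, y, sd = agg["x"].to_numpy(), agg["mean"].to_numpy(), agg["sd"].to_numpy()
    n_par = 3 + (0 if fix_lambda else 1)
    if x.size < n_par:
        raise FitError(f"under-determined: {x.size} points for {n_par} parameters")

    # data-driven starting point: asymptotes from the curve edges, Kd from
    # the half-crossing concentration
    r0, r1 = float(y[0]), float(y[-1])
    half = (r0 + r1) / 2.0
    k0 = float(np.interp(half, y, x)) if r1 > r0 else float(np.median(x))
    k0 = min(max(k0, x[0] * 1e-3), x[-1] * 1e3)

    params = lmfit.Parameters()
    params.add("log_kd", value=math.log(k0), min=math.log(x[0]) - 14, max=math.log(x[-1]) + 14)
    span = max(r1 - r0, 1e-6)
    params.add("r_min", value=r0, min=r0 - 2 * span - 0.5, max=r1 + 2 * span + 0.5)
    params.add("r_max", value=r1, min=r0 - 2 * span - 0.5, max=r1 + 2 * span + 0.5)
    params.add("lam", value=lam, vary=not fix_lambda, min=0.05, max=20.0)

    w = np.where(sd > 0, sd, np.nanmax(sd) if np.any(sd > 0) else 1.0) if weighted else None

    def residual(pars):
        lb = quadratic_bound_fraction(x, math.exp(pars["log_kd"].value), series.tracer_conc)
        model = anisotropy_from_bound_fraction(lb, pars["r_min"].value, pars["r_max"].value,
                                               pars["lam"].value)
        res = model - y
        return res / w if w is not None else res

    out = lmfit.minimize(residual, params, method="least_squares")
    _check_converged(out, "direct titration")
    kd = math.exp(out.params["log_kd"].value)
    kd_err = None
    if out.params["log_kd"].stderr is not None:
        kd_err = kd * out.params["log_kd"].stderr  # delta method on log scale
    return DirectFitResult(
        Kd=kd,
        r_min=out.params["r_min"].value,
        r_max=out.params["r_max"].value,
        lam=out.params["lam"].value,
        Kd_stderr=kd_err,
        r_min_stderr=out.params["r_min"].stderr,
        r_max_stderr=out.params["r_max"].stderr,
        residual_sum=float(np.sum(np.asarray(out.residual) ** 2)),
        converged=bool(out.success),
    )


def _fit_4pl_once(x, y, restrain_low, rmin_value, x0_start):
    params = lmfit.Parameters()
    params.add("log_x0", value=math.log(x0_start),
               min=math.log(x[0]) - 10, max=math.log(x[-1]) + 10)
    params.add("p", value=1.0, min=0.05, max=10.0)
    span = max(abs(y[0] - y[-1]), 1e-4)
    params.add("high", value=float(y[0]), min=min(y) - 2 * span, max=max(y) + 2 * span)
    if restrain_low:
        params.add("low", value=rmin_value, vary=False)
    else:
        params.add("low", value=float(y[-1]), min=min(y) - 2 * span, max=max(y) + 2 * span)

    def residual(pars):
        return logistic_curve(x, math.exp(pars["log_x0"].value), pars["p"].value,
                              pars["low"].value, pars["high"].value) - y

    return lmfit.minimize(residual, params, method="least_squares")


def fit_competition(
    series: TitrationSeries,
    restrain_rmin: bool = False,
    rmin_value: float = -0.03,
    noise_tolerance: float = 0.01,
) -> CompetitionFitResult:
    """Four-parameter logistic fit of mean anisotropy vs competitor.

    The displacement curve runs from the zero-competitor anisotropy (reported
    as r_max) down to the full-displacement floor (r_min).  When a peptide
    does not reach full displacement the floor can be fixed at the value
    observed for peptides that did (``restrain_rmin`` with ``rmin_value``,
    -0.03 anisotropy units by default).

    IC50_sd is the SD of per-replicate-curve fits when >= 2 full replicate
    sets exist; IC50_stderr is the asymptotic error from the mean-curve fit.
    Deterministic multi-start (3 midpoint guesses) makes the optimiser
    robust to poor initialisation.
    """
    if series.mode != "competition":
        raise AnisotropyError("fit_competition requires a competition-mode series")
    agg = aggregate_replicates(series)
    x, y = agg["x"].to_numpy(), agg["mean"].to_numpy()
    if x.size < (3 if restrain_rmin else 4):
        raise FitError("under-determined: too few concentrations for a 4PL fit")

    # descending displacement curve: flag non-monotone data beyond noise
    increases = np.diff(y)
    monotonicity_warning = bool(np.any(increases > noise_tolerance))
    # a displacement window smaller than the noise tolerance means the data
    # are effectively flat — the midpoint is not meaningful
    if abs(y[0] - y[-1]) < noise_tolerance:
        monotonicity_warning = True

    half = (y[0] + y[-1]) / 2.0
    x0_half = float(np.interp(half, y[::-1], x[::-1])) if y[0] > y[-1] else float(np.median(x))
    x0_half = min(max(x0_half, x[0]), x[-1])
    starts = [x0_half, x0_half / 5.0, x0_half * 5.0]

    best = None
    for s in starts:
        try:
            out = _fit_4pl_once(x, y, restrain_rmin, rmin_value, s)
        except Exception:
            continue
        if out.success and (best is None or
                            np.sum(np.asarray(out.residual) ** 2)
                            < np.sum(np.asarray(best.residual) ** 2)):
            best = out
    if best is None:
        raise FitError("competition fit did not converge from any start")

    ic50 = math.exp(best.params["log_x0"].value)
    if ic50 > x[-1] * 10:
        monotonicity_warning = True  # effectively flat: midpoint beyond data

    ic50_sd = None
    n_rep = series.n_replicates
    if n_rep >= 2 and all(len(r) == n_rep for r in series.reads):
        per_rep = []
        reps_matrix = np.array(series.anisotropies())  # (n_x, n_rep)
        for k in range(n_rep):
            try:
                o = _fit_4pl_once(x, reps_matrix[:, k], restrain_rmin, rmin_value, x0_half)
                if o.success:
                    per_rep.append(math.exp(o.params["log_x0"].value))
            except Exception:
                continue
        if len(per_rep) >= 2:
            ic50_sd = float(np.std(per_rep, ddof=1))

    ic50_err = None
    if best.params["log_x0"].stderr is not None:
        ic50_err = ic50 * best.params["log_x0"].stderr

    low, high = best.params["low"].value, best.params["high"].value
    return CompetitionFitResult(
        IC50=ic50,
        hill=best.params["p"].value,
        r_min=min(low, high),
        r_max=max(low, high),
        restrained_rmin=restrain_rmin,
        IC50_sd=ic50_sd,
        IC50_stderr=ic50_err,
        residual_sum=float(np.sum(np.asarray(best.residual) ** 2)),
        converged=True,
        monotonicity_warning=monotonicity_warning,
    )


def delta_delta_g(ic50_ref: float, ic50_new: float, temperature: float = 298.15) -> float:
    """Potency difference as free energy, kJ/mol: -R*T*ln(IC50_new/IC50_ref).

    Positive when the new inhibitor is more potent (smaller IC50).
    """
    if ic50_ref <= 0 or ic50_new <= 0:
        raise AnisotropyError("IC50 values must be positive")
    if temperature <= 0:
        raise AnisotropyError("temperature must be positive")
    return -GAS_CONSTANT_J * temperature * math.log(ic50_new / ic50_ref) / 1000.0
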