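# Methods

This note records the models implemented in `pepstaple`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer should know about.

## Peptide model and variant design

Peptides are numbered by parent-protein position, 1-based and inclusive at
both ends (a "73–94" peptide spans residues 73…94); a 0-based local index is
kept internally.  Phosphoserine (`pS`) is a distinct residue code counting
as one residue everywhere.  The i,i+4 cysteine scan enumerates every ordered
pair (i, i+spacing) inside a caller-chosen region, excluding a caller-chosen
hot-spot set and positions already cysteine.  The hot-spot set is never
inferred: which residues are excluded is an experimental design decision
(energetically critical interface residues — for the N-Myc epitope Glu73,
Trp77, Trp88), and the exact exclusion set determines the variant count, so
both region and hot-spots are explicit parameters with no hidden defaults.

Chemistry bookkeeping: the backbone amide-bond count of an r-residue peptide
is (r − 1) + 1 per capped terminus — so r + 1 for the usual
acetyl/amide peptide; free termini subtract one each.  Molar extinction for
concentration determination is 5600 M⁻¹cm⁻¹ per tryptophan plus
1700 M⁻¹cm⁻¹ for a maleimide-bridged constraint; the disulfide and
free-thiol constraint states carry no extra chromophore and change no
counts.  The maleimide coefficient is treated as additive at the
concentration-determination wavelength.  `average_mass` combines biopython's
average residue masses with nominal modification deltas (acetyl +42.04,
C-terminal amide −0.98, phospho +79.98, maleimide bridge +94.04, disulfide
−2.02); it is bookkeeping for MRE normalisation, not analytical
mass-spectrometry support.

## Fluorescence anisotropy

Anisotropy is computed as r = (S − GP)/(S + 2GP), the standard form whose
denominator is the total intensity I = 2PG + S.  Bound fraction and
anisotropy interconvert through
L_b = (r − r_min)/(λ(r_max − r) + r − r_min); the intensity-change factor λ
defaults to 1 (fluorescein tracers typically show no intensity change on
binding) and can be fixed or floated in the direct fit.  Bound-fraction
values are clamped to [0, 1]; overshoot beyond 5% of the anisotropy window
(configurable) raises a warning first.

**Direct titration.**  The tracer bound fraction follows the Morrison
tight-binding quadratic, evaluated in the conjugate form
L_b = 2x/(b + √(b² − 4x·FL)) with b = x + FL + K_d, which is stable as
FL → 0 and collapses there to the hyperbolic isotherm x/(x + K_d).  The fit
estimates (K_d, r_min, r_max) by bounded least squares on per-concentration
replicate means (lmfit/least_squares), with K_d parameterised on the log
scale; its standard error is delta-method-propagated back.  Starting values
come from the curve edges and the half-crossing concentration.

**Competition.**  Displacement curves are fitted with a direction-agnostic
four-parameter logistic y = A∞ + (A0 − A∞)/(1 + (x/x0)^p), p > 0, so the
zero-competitor asymptote A0 is always identified with r_max and the
full-displacement floor with r_min regardless of how a sign convention
writes the equation.  For peptides that do not reach full displacement the
floor can be fixed at the value observed for peptides that do
(−0.03 anisotropy units in this assay).  Fits are unweighted on replicate
means (a weighted option exists); IC50 uncertainty is reported two ways —
the asymptotic standard error of the mean-curve fit, and the SD of
per-replicate-curve fits when full replicate sets exist, which matches how
triplicate assays are usually summarised.  A deterministic 3-point
multi-start on the midpoint (half-crossing, ±0.7 decades) makes the
optimiser initialisation-robust.  Data that rise by more than a noise
tolerance (default 0.01 anisotropy units) along a supposed displacement
curve, or whose total displacement window is smaller than that tolerance,
set a warning flag rather than failing.

ΔΔG = −RT·ln(IC50_new/IC50_ref) with R = 8.314 J mol⁻¹ K⁻¹ and T defaulting
to 298.15 K (assays equilibrate at room temperature); positive values mean
improvement.  Replicate aggregation reports the per-concentration sample SD
(0 for single replicates); the alternative reading of "average SD" (across
concentrations) is left to the caller since both views are in the report.

## Circular dichroism

Two different chain-length parameters coexist and are deliberately kept in
separate metadata fields: MRE normalisation divides by the *residue count*,
while the helicity estimate's finite-length correction (1 − 3/n) uses the
*amide-bond count* (residues + 1 for capped peptides).  Only this pairing
reproduces a consistent helicity column across 14–29-residue peptides,
including the phosphoserine variant (which behaves as 17 residues / 18
amides).  The mm-pathlength convention in MRE absorbs the usual factor of
10.  MRE at 222 nm is read at the nearest grid point (spectra are collected
on 1 nm grids); no smoothing is applied.  Blank subtraction is mandatory —
an explicit zero blank is available for pre-subtracted data.  The coil
baseline is MRE_coil = 640 − 45T (T in °C; 415 at 5 °C) and the
infinite-helix limit −42500 deg cm² dmol⁻¹ res⁻¹.

## NMR secondary shifts

Δδ = δ_obs − δ_RC per residue and nucleus, with missing nuclei propagating
as NaN.  Maleimide-linked cysteine (`C-mal`) resolves to the plain cysteine
reference — there is no published random-coil value for the modified
residue, so its Δδ can be out of trend; a flag excludes such residues from
segment calling without masking their values.  Segment calling reports
maximal runs of ≥ 4 consecutive residues (one helical turn, configurable)
with Δδ_Cα > 0.1 ppm (or Δδ_Hα < −0.1 ppm in Hα mode); an assignment gap
breaks a run.  The 0.1 ppm threshold and run length are this package's
defaults for what counts as "sustained" — the underlying qualitative rule —
and are exposed as parameters.  Strength bands for Δδ_Cα: < 0.1 ppm
coil-like, 0.1–2.0 ppm weak-helical (typical of transient helices in
disordered peptides), ≥ 2.0 ppm strong-helical (heavily stabilised
helices).  No neighbour- or temperature-corrections are applied to δ_RC by
default; callers can supply any `RandomCoilTable`.  The packaged table holds
approximate literature-consensus values with a provenance note; every
quantitative test uses synthetic tables so that no result depends on it.

## Synthetic data

Generators are pure functions of (parameters, seed) and default to the
screen's assay conditions: 50 nM tracer, 15 μM protein, triplicate wells,
12 log-spaced concentrations spanning 0.01–100× the curve midpoint, i.i.d.
Gaussian noise of SD 0.003 anisotropy units added to anisotropy values
(the assay fits anisotropy means; a P/S-level noise mode is available
through the plate writer, which synthesises consistent P/S pairs at fixed
total intensity).

The competitive-equilibrium simulator solves the exact two-ligand one-site
mass balance for free protein by Brent root-finding on a bracketing
interval [0, P_total] to machine precision, and records the bisection-found
half-displacement concentration as ground truth; with zero competitor it
reduces to the single-ligand quadratic (agreement < 10⁻⁸), and a 4PL fitted
to its noiseless curves leaves < 3% RMS residual over the anisotropy window
under the assay conditions.  CD simulation mixes smooth helix/coil basis
shapes whose 222 nm values are pinned so the helicity formula inverts
exactly; only the 222 nm values are contractually meaningful — band widths
and the 193 nm positive lobe are cosmetic.  Shift-profile simulation adds
f_i·amplitude (defaults: +3 ppm Cα, −0.35 ppm Hα at full helix) to a
synthetic coil table.

What the generators do **not** emulate: maleimide exciton coupling near
230 nm, photobleaching or instrument drift, inner-filter effects,
correlated plate-position noise, peak overlap or assignment ambiguity.
Passing round-trip tests therefore demonstrates correctness of the
estimators under their own model assumptions, not robustness to every
artefact of real instruments.

## Problem sizes and verification

The test suite verifies: the full helicity table (13 peptides, both
summary tables) from printed MRE values; noiseless round-trips of all fits
to 10⁻⁶ relative; median IC50 error < 10% over 200 simulated noisy
competition assays; logistic-vs-thermodynamic IC50 agreement within 5%;
segment calls equal to an exhaustive run-scanner on 1000 random profiles;
and enumeration equal to a brute-force pair oracle under randomised
regions/hot-spots (property-based, derandomised).  These sizes keep the
whole suite in seconds while giving the stochastic checks stable medians.

## Known limitations

- G-factor calibration, FRET/quenching corrections and global multi-curve
  fitting are out of scope; the logistic IC50 is conditional on the assay's
  protein/tracer concentrations and is not converted to a competitor K_i.
- The helicity estimate is a two-state (helix/coil) single-wavelength
  model; it is not a substitute for spectral deconvolution, and constrained
  peptides with unusual chromophores (maleimide) can bias MRE₂₂₂.
- One summary count in the original screen (a "7 variants" scan of the
  61–89 helical region) depends on an exclusion set not fully specified;
  brute-force enumeration over region 76–89 excluding the two tryptophan
  hot-spots yields 8 pairs, so the enumerator never hard-codes a count and
  leaves region/hot-spots to the caller.
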