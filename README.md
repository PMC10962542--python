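# pepstaple

Design and biophysical analysis of constrained (stapled) helical peptides —
a reusable Python implementation of the quantitative workflow used to
develop peptide inhibitors of helix-mediated protein–protein interactions,
exemplified by the N-Myc/Aurora-A interface.

Short peptides copied from a helical binding epitope are usually disordered
in solution and bind weakly.  A common optimisation route is *i,i+4
cysteine scanning*: introduce cysteine pairs one helical turn apart at every
non-hot-spot position, bridge them with dibromomaleimide (**mal**), and
compare against the disulfide (**ox**) and free-thiol (**red**) states.
Each variant is then characterised by three orthogonal measurements, all
implemented here:

- **Fluorescence anisotropy (FA).** Polarized intensities give total
  intensity *I* = 2*PG* + *S* and anisotropy *r* = (*S* − *GP*)/(*S* + 2*GP*).
  Direct titrations are fitted with the Morrison tight-binding quadratic
  for the tracer bound fraction
  *L*<sub>b</sub> = ((x + [FL] + K<sub>d</sub>) −
  √((x + [FL] + K<sub>d</sub>)² − 4·x·[FL])) / (2[FL]);
  competition (displacement) titrations with a four-parameter logistic whose
  midpoint is the IC₅₀, optionally restraining the full-displacement floor
  at r<sub>min</sub> = −0.03.  Potency differences convert to
  ΔΔG = −RT ln(IC₅₀ ratio).
- **Circular dichroism (CD).** Blank-subtracted ellipticity is normalised to
  mean residue ellipticity, MRE = (θ<sub>λ</sub> − θ₀)·M<sub>w</sub>/(n·l·c)
  (l in mm, c in mg/mL), and fractional helicity estimated from
  %hel = (MRE₂₂₂ − MRE<sub>coil</sub>)·100 / (−42500·(1 − 3/n)) with
  MRE<sub>coil</sub> = 640 − 45·T and *n* the number of backbone amide bonds
  including the terminal caps.
- **NMR secondary shifts.** Δδ = δ<sub>obs</sub> − δ<sub>RC</sub> per residue
  against a random-coil reference; sustained runs of downfield Δδ<sub>Cα</sub>
  (or upfield Δδ<sub>Hα</sub>) mark helical propensity.

A synthetic-data module generates inputs for every stage with known ground
truth — including an exact competitive-equilibrium solver that serves as a
thermodynamic oracle for the logistic IC₅₀ — so the whole pipeline is
testable without any instrument data.

## Worked example

```python
import pepstaple as ps

# design: scan the C-terminal extension of the 73-94 peptide, avoiding the
# Trp77/Trp88 hot-spots
wt = ps.parse_peptide("Ac-EPPSWVTEMLLENELWGSPAEE-NH2", 73, name="NMyc_73-94")
for v in ps.enumerate_cys_pair_variants(wt, 85, 90, hotspots={77, 88}, state="mal"):
    print(v.constraint.position_i, v.constraint.position_j, v.sequence,
          ps.molar_extinction(v))
# 85 89 EPPSWVTEMLLECELWCSPAEE 12900.0
# 86 90 EPPSWVTEMLLENCLWGCPAEE 12900.0

# CD: helicity from a measured MRE at 222 nm (5 C, 23 amide bonds)
est = ps.percent_helicity(-4235.0, ps.count_backbone_amides(wt), 5.0)
print(est.percent_helicity, est.rounded_percent)   # 12.58 -> 13

# FA: fit a simulated displacement assay and express the potency gain
series = ps.simulate_competition_equilibrium(
    Kd_tracer=1.5e-6, Kd_competitor=3e-6,
    config=ps.SimulationConfig(seed=11, noise_sd_anisotropy=0.003))
fit = ps.fit_competition(series)
print(fit.IC50)                                    # 4.78e-05 (truth 4.67e-05)
print(ps.delta_delta_g(199e-6, 49e-6))             # 3.47 kJ/mol (4-fold gain)
```

The printed extinction coefficients (2 Trp × 5600 + 1700 for the maleimide),
the 13% helicity and the 3.47 kJ/mol for a 4-fold IC₅₀ improvement are the
package's recomputations of the corresponding assay quantities; the fitted
IC₅₀ tracks the exact thermodynamic half-displacement within a few percent.

Runnable narrative scripts live in `examples/` (design scan, competition
fit, CD helicity, NMR shift profiling, end-to-end pipeline), and a thin CLI
exposes the same stages (`pepstaple design|simulate|fa-direct|fa-compete|
cd-helicity|nmr-shifts|report`).

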