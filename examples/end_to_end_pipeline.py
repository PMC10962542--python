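"""Full study pipeline: design -> simulated measurements -> fits -> report.

Builds a two-peptide study on disk (a 200 uM wild type and a 4x more potent
maleimide-constrained variant with CD and NMR data), runs the pipeline and
prints the assembled report table.
"""

import tempfile
from dataclasses import replace
from pathlib import Path

import pandas as pd

import pepstaple as ps
from pepstaple import io as pio
from pepstaple.pipeline import PeptideEntry, RunConfig, run_pipeline, write_report

tmp = Path(tempfile.mkdtemp())

wt = ps.parse_peptide("Ac-EPPSWVTEMLLENELWGSPAEE-NH2", 73, name="wt_73-94")
mal = ps.substitute(ps.substitute(wt, 85, "C"), 89, "C", name="N85C-G89C-mal")
mal = replace(mal, constraint=ps.ConstraintSpec(85, 89, 4, "mal"))

# simulated competition plate with both series
frames = []
for name, ic50 in [("wt_73-94", 200e-6), ("N85C-G89C-mal", 50e-6)]:
    series = ps.simulate_competition_logistic(
        ic50, config=ps.SimulationConfig(seed=13, noise_sd_anisotropy=0.002))
    part = tmp / f"{name}.csv"
    pio.write_plate_csv(part, series, series_id=name)
    frames.append(pd.read_csv(part))
plate = tmp / "plate.csv"
pd.concat(frames).to_csv(plate, index=False)

# CD spectrum and shift table for the constrained variant
cd_path = tmp / "mal_cd.csv"
pio.write_cd_spectrum(cd_path, ps.simulate_cd_spectrum(21.0, 23))
shift_path = tmp / "mal_shifts.tsv"
sim = ps.simulate_shift_profile(
    mal, [1.0 if 76 <= i <= 87 else 0.0 for i in range(73, 95)],
    amplitude_ca=1.0, coil_table=ps.load_packaged_coil_table())
pio.write_shift_table(shift_path, sim.assignments)

config = RunConfig(
    entries=[
        PeptideEntry(peptide=wt, competition_plate=plate, plate_series_id="wt_73-94"),
        PeptideEntry(peptide=mal, competition_plate=plate,
                     plate_series_id="N85C-G89C-mal",
                     cd_spectrum=cd_path, shift_table=shift_path),
    ],
    reference="wt_73-94",
)
report = run_pipeline(config)
write_report(report, tmp / "out")

df = report.to_frame()
with pd.option_context("display.width", 120):
    print(df[["name", "IC50_M", "rounded_helicity", "ddG_kJ_mol",
              "segments", "epsilon"]].to_string(index=False))
# IC50s recover the simulated truths, the constrained variant shows the
# higher helicity and a positive ddG (more potent than the reference), its
# extinction coefficient includes the maleimide term, and the NMR stage
# reports the 76-87 helical segment.
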