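"""Secondary chemical shifts and helical-segment calls for a peptide.

Simulates a partially helical 73-94 peptide (helix population 60% over
residues 76-87, coil elsewhere), computes per-residue d_delta_Ca against the
random-coil reference, calls helical runs and classifies their strength.
"""

import pepstaple as ps

peptide = ps.parse_peptide("Ac-EPPSWVTEMLLENELWGSPAEE-NH2", 73, name="NMyc_73-94")
fractions = [0.6 if 76 <= i <= 87 else 0.0 for i in range(73, 95)]
sim = ps.simulate_shift_profile(peptide, fractions, amplitude_ca=1.5,
                                noise_sd_ppm=0.02,
                                config=ps.SimulationConfig(seed=8))

profile = ps.secondary_shifts(sim.assignments, sim.coil_table)
labels = ps.classify_helix_strength(profile)
for idx, res, dca, lab in zip(profile.residue_index, profile.residue_type,
                              profile.d_delta_ca, labels):
    bar = "+" * max(int(dca * 10), 0)
    print(f"  {idx:3d} {res:>2}  {dca:+.2f} ppm  {lab:14s} {bar}")

segments = ps.call_helical_segments(profile, min_run=4, ca_threshold=0.1)
print("helical segments:", [(s.start, s.end) for s in segments])
# Sustained positive (downfield) Calpha secondary shifts of ~0.9 ppm mark the
# 76-87 stretch as weakly helical; the run-caller reports it as one segment.
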