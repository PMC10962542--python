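"""Design i,i+4 cysteine-pair staple variants of a helical peptide.

Starting from the 61-89 parent peptide, truncate to the helical core plus
its C-terminal extension (73-94) and scan the extension for constraint
sites, avoiding the binding hot-spots Glu73/Trp77/Trp88.
"""

import pepstaple as ps

parent = ps.parse_peptide("Ac-LSPSRGFAEHSSEPPSWVTEMLLENELWG-NH2", 61,
                          name="NMyc_61-89")
core = ps.truncate(parent, 73, 89, name="NMyc_73-89")
print(f"parent {parent.name}: {parent.sequence} ({len(parent)} residues)")
print(f"core   {core.name}: {core.sequence}")

extended = ps.parse_peptide("Ac-EPPSWVTEMLLENELWGSPAEE-NH2", 73, name="NMyc_73-94")
variants = ps.enumerate_cys_pair_variants(extended, 85, 90,
                                          hotspots={77, 88}, state="mal")
print(f"\ncysteine pairs in the 85-90 extension of {extended.name}:")
for v in variants:
    c = v.constraint
    print(f"  {c.position_i}/{c.position_j}  {v.sequence}  "
          f"n_amide={ps.count_backbone_amides(v)}  "
          f"epsilon={ps.molar_extinction(v):.0f} /M/cm")
# Each line is one maleimide-constrainable variant; epsilon includes the
# 1700 /M/cm maleimide term on top of 2 x 5600 for the tryptophans, and
# n_amide is the chain-length parameter the CD helicity formula needs.
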