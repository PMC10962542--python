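import numpy as np
import pytest
from hypothesis import settings

import pepstaple as ps

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")

# The screen's summary rows: name, sequence string, parent offset, measured
# MRE at 222 nm (deg cm^2 dmol^-1 res^-1, 5 C) and the reported % helicity.
TABLE_ROWS = [
    ("NMyc_61-89", "Ac-LSPSRGFAEHSSEPPSWVTEMLLENELWG-NH2", 61, -2059, 6),
    ("NMyc_73-89", "Ac-EPPSWVTEMLLENELWG-NH2", 73, -4079, 13),
    ("NMyc_76-89", "Ac-SWVTEMLLENELWG-NH2", 76, -4342, 14),
    ("NMyc_73-94", "Ac-EPPSWVTEMLLENELWGSPAEE-NH2", 73, -4235, 13),
    ("NMyc_73-97", "Ac-EPPSWVTEMLLENELWGSPAEEDAF-NH2", 73, -4886, 14),
    ("NMyc_73-89-E73pS", "Ac-pSPPSWVTEMLLENELWG-NH2", 73, -5394, 16),
    ("NMyc_73-89-E73S", "Ac-SPPSWVTEMLLENELWG-NH2", 73, -5541, 17),
    ("NMyc_73-94-N85C/G89C-red", "Ac-EPPSWVTEMLLECELWCSPAEE-NH2", 73, -4383, 13),
    ("NMyc_73-94-N85C/G89C-ox", "Ac-EPPSWVTEMLLECELWCSPAEE-NH2", 73, -5255, 15),
    ("NMyc_73-94-N85C/G89C-mal", "Ac-EPPSWVTEMLLECELWCSPAEE-NH2", 73, -7223, 21),
    ("NMyc_73-94-E86C/S90C-red", "Ac-EPPSWVTEMLLENCLWGCPAEE-NH2", 73, -6397, 18),
    ("NMyc_73-94-E86C/S90C-ox", "Ac-EPPSWVTEMLLENCLWGCPAEE-NH2", 73, -7454, 21),
    ("NMyc_73-94-E86C/S90C-mal", "Ac-EPPSWVTEMLLENCLWGCPAEE-NH2", 73, -5715, 17),
]


@pytest.fixture
def nmyc_73_94():
    return ps.parse_peptide("Ac-EPPSWVTEMLLENELWGSPAEE-NH2", 73, name="NMyc_73-94")


@pytest.fixture
def nmyc_61_89():
    return ps.parse_peptide("Ac-LSPSRGFAEHSSEPPSWVTEMLLENELWG-NH2", 61, name="NMyc_61-89")


def brute_force_cys_pairs(p, region_start, region_end, hotspots, spacing):
    """Independent exhaustive enumeration of admissible (i, i+spacing) pairs."""
    pairs = []
    for i in range(region_start, region_end + 1):
        j = i + spacing
        if j > region_end:
            continue
        if i in hotspots or j in hotspots:
            continue
        if p.residue_at(i) == "C" or p.residue_at(j) == "C":
            continue
        pairs.append((i, j))
    return pairs


def brute_force_runs(indices, passing, min_run):
    """Independent run-scanner: maximal runs of >= min_run consecutive
    parent indices whose residue passes; returns (start, end) pairs."""
    passing_set = {i for i, ok in zip(indices, passing) if ok}
    runs = []
    for i in sorted(passing_set):
        if i - 1 in passing_set:
            continue
        j = i
        while j + 1 in passing_set:
            j += 1
        if j - i + 1 >= min_run:
            runs.append((i, j))
    return runs
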