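import pytest
from hypothesis import given, strategies as st

import pepstaple as ps
from pepstaple.peptides import PeptideError, PeptideParseError

from conftest import TABLE_ROWS, brute_force_cys_pairs


class TestParse:
    @pytest.mark.parametrize("name,seq,offset,_mre,_hel", TABLE_ROWS)
    def test_table_sequences_parse(self, name, seq, offset, _mre, _hel):
        p = ps.parse_peptide(seq, offset, name=name)
        assert p.n_term == "acetyl" and p.c_term == "amide"
        # residue count = token count (pS is one residue)
        body = seq.removeprefix("Ac-").removesuffix("-NH2")
        assert len(p) == len(body) - body.count("pS")
        assert p.parent_end == offset + len(p) - 1

    def test_phosphoserine_token(self):
        p = ps.parse_peptide("Ac-pSPPSWVTEMLLENELWG-NH2", 73)
        assert len(p) == 17
        assert p.residue_at(73) == "pS"

    def test_fam_ahx_prefix_and_free_termini(self):
        p = ps.parse_peptide("FAM-Ahx-EPPSW", 73)
        assert p.n_term == "FAM-Ahx" and p.c_term == "free"
        q = ps.parse_peptide("EPPSW", 73)
        assert q.n_term == "free" and q.c_term == "free"

    @pytest.mark.parametrize("bad", ["", "Ac--NH2", "   "])
    def test_degenerate_strings_rejected(self, bad):
        with pytest.raises(PeptideParseError):
            ps.parse_peptide(bad, 1)

    def test_unknown_token_named_with_position(self):
        with pytest.raises(PeptideParseError, match="'X'.*position 3"):
            ps.parse_peptide("Ac-EPPXW-NH2", 73)


class TestTruncateSubstitute:
    def test_truncation_to_helical_core(self, nmyc_61_89):
        t = ps.truncate(nmyc_61_89, 73, 89)
        assert t.sequence == "EPPSWVTEMLLENELWG"
        assert t.numbering_offset == 73
        t2 = ps.truncate(nmyc_61_89, 76, 89)
        assert t2.sequence == "SWVTEMLLENELWG" and len(t2) == 14

    def test_truncate_full_range_is_identity(self, nmyc_61_89):
        t = ps.truncate(nmyc_61_89, 61, 89)
        assert t.residues == nmyc_61_89.residues
        assert t.numbering_offset == 61

    def test_truncate_composition(self, nmyc_61_89):
        once = ps.truncate(nmyc_61_89, 70, 85)
        twice = ps.truncate(once, 73, 82)
        assert twice.residues == ps.truncate(nmyc_61_89, 73, 82).residues
        assert twice.numbering_offset == 73

    def test_truncate_out_of_range(self, nmyc_61_89):
        with pytest.raises(PeptideError):
            ps.truncate(nmyc_61_89, 50, 89)
        with pytest.raises(PeptideError):
            ps.truncate(nmyc_61_89, 80, 73)

    def test_phospho_substitution(self):
        p = ps.parse_peptide("Ac-EPPSWVTEMLLENELWG-NH2", 73)
        q = ps.substitute(p, 73, "pS")
        assert q.sequence.startswith("pSPPS")
        assert len(q) == len(p)

    def test_substitute_self_is_identity(self, nmyc_73_94):
        assert ps.substitute(nmyc_73_94, 77, "W").residues == nmyc_73_94.residues

    def test_double_cys_substitution_matches_screen_variant(self, nmyc_73_94):
        q = ps.substitute(ps.substitute(nmyc_73_94, 85, "C"), 89, "C")
        assert q.sequence == "EPPSWVTEMLLECELWCSPAEE"

    def test_substitute_errors(self, nmyc_73_94):
        with pytest.raises(PeptideError):
            ps.substitute(nmyc_73_94, 60, "A")
        with pytest.raises(PeptideError):
            ps.substitute(nmyc_73_94, 77, "Z")


class TestCysPairScan:
    def test_c_terminal_extension_pairs(self, nmyc_73_94):
        variants = ps.enumerate_cys_pair_variants(nmyc_73_94, 85, 90, hotspots={77, 88})
        pairs = [(v.constraint.position_i, v.constraint.position_j) for v in variants]
        assert pairs == [(85, 89), (86, 90)]
        assert [v.sequence for v in variants] == [
            "EPPSWVTEMLLECELWCSPAEE", "EPPSWVTEMLLENCLWGCPAEE"]

    def test_region_narrower_than_spacing(self, nmyc_73_94):
        assert ps.enumerate_cys_pair_variants(nmyc_73_94, 85, 88) == []

    def test_helical_region_scan_matches_oracle(self, nmyc_61_89):
        variants = ps.enumerate_cys_pair_variants(nmyc_61_89, 76, 89, hotspots={77, 88})
        pairs = [(v.constraint.position_i, v.constraint.position_j) for v in variants]
        assert pairs == brute_force_cys_pairs(nmyc_61_89, 76, 89, {77, 88}, 4)
        assert len(pairs) == 8

    def test_region_outside_peptide(self, nmyc_73_94):
        with pytest.raises(PeptideError):
            ps.enumerate_cys_pair_variants(nmyc_73_94, 60, 90)

    @given(
        start=st.integers(61, 80),
        width=st.integers(0, 9),
        hotspots=st.sets(st.integers(61, 89), max_size=6),
        spacing=st.integers(1, 6),
    )
    def test_scan_equals_oracle_and_variants_valid(self, start, width, hotspots, spacing):
        p = ps.parse_peptide("Ac-LSPSRGFAEHSSEPPSWVTEMLLENELWG-NH2", 61)
        end = min(start + width, 89)
        variants = ps.enumerate_cys_pair_variants(p, start, end, hotspots, spacing)
        pairs = [(v.constraint.position_i, v.constraint.position_j) for v in variants]
        assert pairs == brute_force_cys_pairs(p, start, end, hotspots, spacing)
        for v in variants:
            # PeptideSpec invariants: constraint anchors are Cys, spacing holds
            assert v.residue_at(v.constraint.position_i) == "C"
            assert v.residue_at(v.constraint.position_j) == "C"
            assert v.constraint.position_j - v.constraint.position_i == spacing


class TestChemistryBookkeeping:
    @pytest.mark.parametrize("r", [1, 2, 5, 14, 22, 29])
    def test_amide_count_is_residues_plus_one_for_capped(self, r):
        p = ps.PeptideSpec(name="x", residues=("A",) * r)
        assert ps.count_backbone_amides(p) == r + 1

    def test_free_termini_each_subtract_one(self):
        res = ("A",) * 5
        assert ps.count_backbone_amides(
            ps.PeptideSpec("x", res, n_term="free")) == 5
        assert ps.count_backbone_amides(
            ps.PeptideSpec("x", res, c_term="free")) == 5
        assert ps.count_backbone_amides(
            ps.PeptideSpec("x", res, n_term="free", c_term="free")) == 4

    def test_phospho_counts_as_one_residue(self):
        p = ps.parse_peptide("Ac-pSPPSWVTEMLLENELWG-NH2", 73)
        assert ps.count_backbone_amides(p) == 18

    def test_extinction_two_trp(self, nmyc_73_94):
        assert ps.molar_extinction(nmyc_73_94) == 11200.0

    def test_extinction_maleimide_adds_1700(self, nmyc_73_94):
        from pepstaple import ConstraintSpec
        mal = ps.substitute(ps.substitute(nmyc_73_94, 85, "C"), 89, "C")
        from dataclasses import replace
        mal = replace(mal, constraint=ConstraintSpec(85, 89, 4, "mal"))
        assert ps.molar_extinction(mal) == 12900.0
        # red and ox states do not carry the chromophore
        for state in ("red", "ox"):
            v = replace(mal, constraint=ConstraintSpec(85, 89, 4, state))
            assert ps.molar_extinction(v) == 11200.0

    def test_extinction_no_chromophores(self):
        p = ps.PeptideSpec("x", tuple("ALAEK"))
        assert ps.molar_extinction(p) == 0.0

    @pytest.mark.parametrize("A,eps,expected", [
        (0.0, 5600, 0.0),
        (0.56, 5600, 100e-6),
        (1.29, 12900, 100e-6),
    ])
    def test_beer_lambert(self, A, eps, expected):
        assert ps.concentration_from_absorbance(A, eps, 1.0) == pytest.approx(expected)

    def test_beer_lambert_rejects_zero_epsilon(self):
        with pytest.raises(PeptideError):
            ps.concentration_from_absorbance(0.5, 0.0)

    def test_average_mass_tracks_modifications(self, nmyc_73_94):
        base = ps.average_mass(nmyc_73_94)
        assert 2400 < base < 2600  # 22-residue Ac/NH2 peptide
        phospho = ps.average_mass(ps.substitute(nmyc_73_94, 76, "pS"))
        assert phospho == pytest.approx(base + 79.98, abs=0.1)


class TestInvariants:
    def test_constraint_must_anchor_on_cysteines(self, nmyc_73_94):
        from pepstaple import ConstraintSpec
        from dataclasses import replace
        with pytest.raises(PeptideError, match="not Cys"):
            replace(nmyc_73_94, constraint=ConstraintSpec(85, 89, 4, "red"))

    def test_constraint_spacing_must_match(self):
        from pepstaple import ConstraintSpec
        with pytest.raises(PeptideError):
            ConstraintSpec(85, 89, spacing=3)

    def test_empty_and_bad_offset_rejected(self):
        with pytest.raises(PeptideError):
            ps.PeptideSpec("x", ())
        with pytest.raises(PeptideError):
            ps.PeptideSpec("x", ("A",), numbering_offset=0)
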