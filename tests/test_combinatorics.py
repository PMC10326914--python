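"""Digestion, isomer enumeration, signatures and marker uniqueness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pcovms as pm
from pcovms.combinatorics import (
    DigestSpec,
    EXACT_TOL,
    digest,
    isomer_consistent_with_digest,
    signature_1d,
    signature_2d,
)

from conftest import oracle_signatures, oracle_unique, random_peptide


class TestDigest:
    def test_trypsin_proline_rule(self):
        # cleave after K2 (R3 blocked by P4), after K6
        peps = digest("AKRPGKE", DigestSpec("trypsin", min_length=2))
        assert [p.sequence for p in peps] == ["AK", "RPGK"]

    def test_glu_c(self):
        peps = digest("AEGEDK", DigestSpec("glu-c", min_length=2))
        assert [p.sequence for p in peps] == ["AE", "GE", "DK"]

    def test_glu_c_with_d(self):
        peps = digest("AEGEDK", DigestSpec("glu-c", min_length=2, glu_c_cleaves_d=True))
        assert [p.sequence for p in peps] == ["AE", "GE"]  # D and K singletons dropped

    def test_no_sites_whole_sequence(self):
        peps = digest("AGAGAG", DigestSpec("trypsin", min_length=2))
        assert [p.sequence for p in peps] == ["AGAGAG"]

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(ValueError):
            DigestSpec("pepsin")

    def test_missed_cleavages(self):
        peps = digest("AKGKV", DigestSpec("trypsin", missed_cleavages=1, min_length=2))
        assert "AKGK" in [p.sequence for p in peps]

    def test_blocking_modification_extends_candidates(self):
        # H4 4-17 spans three internal K cleavage sites; only reachable
        # when acetylation suppresses them
        h4_region = "SGRGKGGKGLGKGGAKRHRKV"
        spec = DigestSpec("trypsin", min_length=6, max_length=20)
        plain = {p.sequence for p in digest(h4_region, spec)}
        blocked = {p.sequence for p in digest(h4_region, spec, pm.ACETYL)}
        assert pm.H4_4_17 not in plain
        assert pm.H4_4_17 in blocked

    def test_isomer_digest_consistency(self):
        h4_region = "SGRGKGGKGLGKGGAKRHRKV"
        spec = DigestSpec("trypsin", min_length=6, max_length=20)
        pep = next(
            p for p in digest(h4_region, spec, pm.ACETYL) if p.sequence == pm.H4_4_17
        )
        # all four internal K sites modified -> consistent; two -> not
        assert isomer_consistent_with_digest(pep, (2, 5, 9, 13), spec, pm.ACETYL)
        assert not isomer_consistent_with_digest(pep, (5, 13), spec, pm.ACETYL)


class TestEnumerateIsomers:
    def test_h4_diacetyl_has_six_isomers(self):
        iso = pm.enumerate_isomers(pm.H4_4_17, pm.ACETYL, 2, parent_offset=4)
        assert len(iso) == 6
        assert {i.sites for i in iso.isomers} == {
            (2, 5), (2, 9), (2, 13), (5, 9), (5, 13), (9, 13)
        }

    @pytest.mark.parametrize("m, n", [(0, 1), (4, 1)])
    def test_degenerate_multiplicities(self, m, n):
        assert len(pm.enumerate_isomers(pm.H4_4_17, pm.ACETYL, m)) == n

    def test_multiplicity_exceeding_sites_rejected(self):
        with pytest.raises(ValueError):
            pm.enumerate_isomers("GKGA", pm.ACETYL, 2)

    def test_isomers_share_precursor_mass(self, h4_all):
        masses = [pm.peptide_neutral_mass(i) for i in h4_all.isomers]
        assert np.ptp(masses) < 1e-9


class TestSignatures:
    def test_p4_signature_contains_acetylated_y5(self, h4_p1_p4, p4):
        y5_ac = pm.fragment_mz(p4, "y", (10, 14))
        sigs = signature_1d(h4_p1_p4, ("b", "y"))
        assert any(abs(v - y5_ac) < EXACT_TOL for v in sigs[3])

    def test_p2_has_unmodified_y5_only(self, h4_p1_p4):
        bare = pm.ModifiedPeptide(pm.H4_4_17)
        y5 = pm.fragment_mz(bare, "y", (10, 14))
        y5_ac = y5 + 42.010565
        sigs = signature_1d(h4_p1_p4, ("b", "y"))
        assert any(abs(v - y5) < 1e-4 for v in sigs[1])
        assert not any(abs(v - y5_ac) < 1e-4 for v in sigs[1])

    def test_all_isomers_share_b1(self, h4_p1_p4):
        b1 = pm.fragment_mz(pm.ModifiedPeptide(pm.H4_4_17), "b", (1, 1))
        for sig in signature_1d(h4_p1_p4, ("b", "y")):
            assert any(abs(v - b1) < EXACT_TOL for v in sig)

    def test_p4_pair_and_p2_lack_of_it(self, h4_p1_p4, p4):
        pair = (
            pm.fragment_mz(p4, "internal_b", (3, 8)),
            pm.fragment_mz(p4, "y", (10, 14)),
        )
        sigs = signature_2d(h4_p1_p4)
        def has(sig):
            return any(
                abs(a - pair[0]) < 1e-4 and abs(b - pair[1]) < 1e-4 for a, b in sig
            )
        assert has(sigs[3]) and not has(sigs[1])

    def test_no_self_pairs(self, h4_p1_p4):
        for sig in signature_2d(h4_p1_p4):
            for a, b in sig:
                assert b - a > -EXACT_TOL

    def test_pair_spans_disjoint(self, p4):
        for fa, fb in pm.correlation_pairs(p4):
            assert fa.span[1] < fb.span[0] or fb.span[1] < fa.span[0]


class TestUniqueMarkers:
    def test_p4_no_unique_1d_even_with_internals(self, h4_p1_p4):
        rep = pm.find_unique_markers(
            h4_p1_p4, "1d", kinds_1d=("b", "y", "internal_b")
        )
        assert rep.unique[3] == ()
        assert rep.identifiable == [True, True, False, False]

    def test_p4_unique_2d_contains_marker_pair(self, h4_p1_p4, p4):
        rep = pm.find_unique_markers(h4_p1_p4, "2d")
        pair = (
            pm.fragment_mz(p4, "internal_b", (3, 8)),
            pm.fragment_mz(p4, "y", (10, 14)),
        )
        assert any(
            abs(a - pair[0]) < 1e-4 and abs(b - pair[1]) < 1e-4
            for a, b in rep.unique[3]
        )

    def test_marker_pair_maps_to_exactly_one_isomer(self, h4_p1_p4, p4):
        pair = (
            pm.fragment_mz(p4, "internal_b", (3, 8)),
            pm.fragment_mz(p4, "y", (10, 14)),
        )
        sigs = signature_2d(h4_p1_p4)
        owners = [
            i
            for i, sig in enumerate(sigs)
            if any(abs(a - pair[0]) < 1e-4 and abs(b - pair[1]) < 1e-4 for a, b in sig)
        ]
        assert owners == [3]

    def test_single_site_difference_all_identifiable_1d(self):
        iso = pm.enumerate_isomers("GAKGKAG", pm.ACETYL, 1)
        rep = pm.find_unique_markers(iso, "1d")
        assert all(rep.identifiable)

    def test_bad_tolerance_rejected(self, h4_p1_p4):
        with pytest.raises(ValueError):
            pm.find_unique_markers(h4_p1_p4, "1d", tolerance=0.0)

    def test_single_isomer_rejected(self):
        iso = pm.enumerate_isomers("GKGA", pm.ACETYL, 1)
        with pytest.raises(ValueError):
            pm.find_unique_markers(iso, "1d")


class TestOracleAgreement:
    """The uniqueness engine agrees with the brute-force cross-product
    oracle on small peptides."""

    @pytest.mark.parametrize("seed", range(8))
    def test_small_peptides(self, seed):
        rng = np.random.default_rng(1000 + seed)
        seq = random_peptide(rng, int(rng.integers(6, 9)), 3)
        iso = pm.enumerate_isomers(seq, pm.ACETYL, 2)
        assert len(iso) == 3
        combos = [i.sites for i in iso.isomers]
        for mode in ("1d", "2d"):
            rep = pm.find_unique_markers(iso, mode)
            got = [
                {
                    round(u, 6) if mode == "1d" else (round(u[0], 6), round(u[1], 6))
                    for u in uu
                }
                for uu in rep.unique
            ]
            expected = oracle_unique(oracle_signatures(seq, combos, mode))
            assert got == expected, f"{seq} mode={mode}"


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_unique_1d_implies_unique_2d(seed):
    """A unique fragment paired with any disjoint partner gives a unique
    pair, so 1D identifiability implies 2D identifiability."""
    rng = np.random.default_rng(seed)
    seq = random_peptide(rng, int(rng.integers(8, 16)), int(rng.integers(2, 5)))
    iso = pm.enumerate_isomers(seq, pm.ACETYL, 2)
    if len(iso) < 2:
        return
    rep1 = pm.find_unique_markers(iso, "1d")
    rep2 = pm.find_unique_markers(iso, "2d")
    for id1, id2 in zip(rep1.identifiable, rep2.identifiable):
        assert (not id1) or id2


class TestCountIdentifiable:
    def test_h4_region_survey(self):
        # two missed cleavages: a diacetyl isomer blocks 2 of the 4
        # internal K sites, the other two count as missed
        table = pm.count_identifiable(
            {"H4": "SGRGKGGKGLGKGGAKRHRKV"},
            DigestSpec("trypsin", missed_cleavages=2, min_length=6, max_length=20),
            pm.ACETYL,
            m_values=(2,),
        )
        row = table[table.peptide == pm.H4_4_17]
        assert len(row) == 1
        assert int(row.n_isomers.iloc[0]) == 6
        assert int(row.n_id_2d.iloc[0]) >= int(row.n_id_1d.iloc[0])

    def test_empty_input(self):
        table = pm.count_identifiable({}, DigestSpec("trypsin"), pm.ACETYL)
        assert table.empty
        assert list(table.columns) == [
            "protein_id", "peptide", "start", "m", "n_isomers", "n_id_1d", "n_id_2d"
        ]

    def test_no_lysines_no_rows(self):
        table = pm.count_identifiable(
            {"x": "AGAGAGAGAG"}, DigestSpec("trypsin"), pm.ACETYL
        )
        assert table.empty
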