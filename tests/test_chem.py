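"""Chemistry core: formula arithmetic, homolog enumeration, neutral-loss
assignment and transition building."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from copepodamides.chem import (
    CA,
    DHCA,
    SULFONATE_FRAGMENT_MZ,
    TAURINE_FRAGMENT_MZ,
    FattyAcyl,
    LipidSpecies,
    Transition,
    UnknownElementError,
    assign_acyl,
    build_transitions,
    enumerate_library,
    fatty_acid_formula,
    fatty_acid_mass,
    format_formula,
    monoisotopic_mass,
    precursor_mz,
    transitions_to_frame,
)

H = 1.00782503207
H2 = 2 * H
CH2 = 12.0 + H2


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula, mode, expected, places",
        [
            ("C2H6NO3S", "cation", 124.0, 1),  # taurine fragment
            ("SO3", "cation", 80.0, 0),  # sulfonate fragment
            ("C22H42NO5S", "cation", 432.0, 0),  # dhCA fragment
            ("C22H40NO5S", "cation", 430.0, 0),  # CA fragment
        ],
    )
    def test_printed_fragment_values(self, formula, mode, expected, places):
        assert round(monoisotopic_mass(formula, mode), places) == expected

    def test_dhca_fragment_exact(self):
        # independent per-atom hand summation: 22*12 + 42*1.00782503
        # + 14.00307 + 5*15.99491 + 31.97207 - m_e = 432.2778
        assert monoisotopic_mass("C22H42NO5S", "cation") == pytest.approx(
            432.278, abs=1e-3
        )

    def test_empty_formula_is_zero(self):
        assert monoisotopic_mass({}) == 0.0

    def test_unknown_element_named_in_error(self):
        with pytest.raises(UnknownElementError, match="Xx"):
            monoisotopic_mass({"Xx": 1})

    def test_cation_subtracts_one_electron(self):
        neutral = monoisotopic_mass("C2H6NO3S")
        cation = monoisotopic_mass("C2H6NO3S", "cation")
        assert neutral - cation == pytest.approx(0.000548579909, abs=1e-12)

    def test_two_path_oracle_dict_vs_string(self):
        """Mass from a count map equals mass from the parsed formula string."""
        counts = {"C": 22, "H": 40, "N": 1, "O": 5, "S": 1}
        assert monoisotopic_mass(counts) == monoisotopic_mass(
            format_formula(counts)
        )

    @pytest.mark.parametrize("formula", ["C22H42NO5S", "C2H6NO3S", "C14H28O2", "SO3"])
    def test_against_pyteomics(self, formula):
        """Independent mass oracle: pyteomics' unified-mass calculator."""
        from pyteomics.mass import calculate_mass

        assert monoisotopic_mass(formula) == pytest.approx(
            calculate_mass(formula=formula), abs=1e-4
        )

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S"]),
            st.integers(0, 50),
            max_size=5,
        ),
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S"]),
            st.integers(0, 50),
            max_size=5,
        ),
    )
    def test_mass_is_additive(self, f1, f2):
        merged = {k: f1.get(k, 0) + f2.get(k, 0) for k in {*f1, *f2}}
        assert monoisotopic_mass(merged) == pytest.approx(
            monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9
        )


class TestFattyAcyl:
    @pytest.mark.parametrize(
        "label, formula",
        [("14:0", "C14H28O2"), ("2:0", "C2H4O2"), ("22:6", "C22H32O2")],
    )
    def test_free_fatty_acid_formula(self, label, formula):
        acyl = FattyAcyl.from_label(label)
        assert format_formula(fatty_acid_formula(acyl)) == formula

    @pytest.mark.parametrize("carbons, dbonds", [(1, 0), (4, 2), (3, 1), (14, -1)])
    def test_invalid_acyls_rejected(self, carbons, dbonds):
        with pytest.raises(ValueError):
            FattyAcyl(carbons, dbonds)

    @given(st.integers(2, 30), st.integers(0, 14))
    def test_label_round_trip(self, carbons, dbonds):
        if dbonds > (carbons - 2) // 2:
            return
        acyl = FattyAcyl(carbons, dbonds)
        assert FattyAcyl.from_label(acyl.label) == acyl


class TestPrecursorMz:
    @pytest.mark.parametrize(
        "scaffold, label, printed",
        [(DHCA, "14:0", 660.5), (CA, "14:0", 658.5), (DHCA, "15:1", 672.5)],
    )
    def test_printed_one_decimal(self, scaffold, label, printed):
        assert round(precursor_mz(scaffold, FattyAcyl.from_label(label)), 1) == printed

    def test_dhca_22_6_independent_summation(self):
        # 432.278 (fragment cation) + 328.240 (DHA) = 760.52
        assert precursor_mz(DHCA, FattyAcyl(22, 6)) == pytest.approx(760.52, abs=0.01)

    @given(st.integers(2, 26), st.integers(0, 12))
    def test_scaffolds_differ_by_two_hydrogens(self, carbons, dbonds):
        if dbonds > (carbons - 2) // 2:
            return
        acyl = FattyAcyl(carbons, dbonds)
        delta = precursor_mz(DHCA, acyl) - precursor_mz(CA, acyl)
        assert delta == pytest.approx(H2, abs=1e-9)

    def test_homolog_mass_ladders(self):
        base = FattyAcyl(18, 2)
        plus_db = FattyAcyl(18, 3)
        plus_ch2 = FattyAcyl(19, 2)
        assert precursor_mz(DHCA, base) - precursor_mz(DHCA, plus_db) == pytest.approx(
            H2, abs=1e-9
        )
        assert precursor_mz(DHCA, plus_ch2) - precursor_mz(DHCA, base) == pytest.approx(
            CH2, abs=1e-9
        )

    def test_precursor_is_fragment_plus_fatty_acid(self):
        sp = LipidSpecies(DHCA, FattyAcyl(20, 5))
        recomputed = DHCA.diagnostic_product_mz + fatty_acid_mass(sp.acyl)
        assert abs(sp.precursor_mz - recomputed) < 1e-6


class TestEnumerateLibrary:
    def test_single_chain_both_scaffolds(self):
        lib = enumerate_library((14, 14), (0, 0))
        assert [(s.name, round(s.precursor_mz, 2)) for s in lib] == [
            ("14:0 CA", 658.47),
            ("14:0 dhCA", 660.49),
        ]

    def test_count_matches_combinatorial_oracle(self):
        lib = enumerate_library((14, 22), (0, 6))
        oracle = 2 * sum(
            len([d for d in range(0, 7) if d <= (c - 2) // 2])
            for c in range(14, 23)
        )
        assert len(lib) == oracle

    def test_smallest_valid_acyl(self):
        lib = enumerate_library((2, 2), (0, 0), scaffolds=[DHCA])
        assert len(lib) == 1 and lib[0].name == "2:0 dhCA"

    def test_sorted_and_deduplicated(self, library):
        keys = [(s.scaffold.name, s.acyl.carbons, s.acyl.double_bonds) for s in library]
        assert keys == sorted(keys) and len(keys) == len(set(keys))


class TestAssignAcyl:
    def test_known_dhca(self, library):
        result = assign_acyl(660.5, 432.3, 0.3, library)
        assert result.status == "ok"
        assert result.best.name == "14:0 dhCA"

    def test_out_of_library_loss(self, library):
        assert assign_acyl(500.0, 432.3, 0.3, library).status == "no_acyl"

    def test_no_scaffold_status(self, library):
        assert assign_acyl(660.5, 300.0, 0.3, library).status == "no_scaffold"

    def test_dha_best_candidate(self, library):
        # brute-force loss matching over the full library
        loss = 760.5 - 432.3
        brute = min(
            (sp for sp in library if sp.scaffold.name == "dhCA"),
            key=lambda sp: abs(loss - fatty_acid_mass(sp.acyl)),
        )
        result = assign_acyl(760.5, 432.3, 0.3, library)
        assert result.best.name == brute.name == "22:6 dhCA"

    def test_negative_loss_rejected(self, library):
        with pytest.raises(ValueError):
            assign_acyl(400.0, 432.3, 0.3, library)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            assign_acyl(660.5, 432.3, 0.0)

    def test_round_trip_over_library_without_collisions(self, library):
        """Every library member is recovered as the unique top candidate from
        its own theoretical precursor and diagnostic product."""
        for sp in library:
            result = assign_acyl(
                sp.precursor_mz, sp.scaffold.diagnostic_product_mz, 0.3, library
            )
            assert result.status == "ok"
            assert result.best.name == sp.name
            assert len(result.candidates) == 1, f"collision at {sp.name}"
            assert abs(result.best_error) < 1e-9


class TestTransitions:
    def test_counts(self, library):
        sp = [library[0]]
        assert len(build_transitions(sp, include_confirmatory=False)) == 1
        trans = build_transitions(sp, include_confirmatory=True)
        assert len(trans) == 3
        assert {t.kind for t in trans} == {"scaffold", "taurine", "sulfonate"}

    def test_confirmatory_products(self, library):
        trans = build_transitions([library[0]], include_confirmatory=True)
        by_kind = {t.kind: t.product_mz for t in trans}
        assert round(by_kind["taurine"], 1) == 124.0
        assert round(by_kind["sulfonate"]) == 80
        assert by_kind["taurine"] == TAURINE_FRAGMENT_MZ
        assert by_kind["sulfonate"] == SULFONATE_FRAGMENT_MZ

    def test_scaffold_products_for_many_species(self, library):
        species = library[:35]
        trans = build_transitions(species, include_confirmatory=False)
        assert len(trans) == 35
        assert all(
            min(abs(t.product_mz - 430.26), abs(t.product_mz - 432.28)) < 0.05
            for t in trans
        )

    def test_product_below_precursor_enforced(self, library):
        with pytest.raises(ValueError):
            Transition(library[0], library[0].precursor_mz + 1.0, "scaffold")

    def test_frame_columns(self, library):
        frame = transitions_to_frame(build_transitions(library[:2], True))
        assert list(frame.columns) == [
            "compound_name", "scaffold", "acyl", "precursor_mz", "product_mz", "kind",
        ]
        assert len(frame) == 6


def test_scaffold_fragments_differ_by_two_hydrogens():
    delta = DHCA.diagnostic_product_mz - CA.diagnostic_product_mz
    assert delta == pytest.approx(H2, abs=1e-9)
    assert abs(DHCA.channel - DHCA.diagnostic_product_mz) < 0.05
    assert abs(CA.channel - CA.diagnostic_product_mz) < 0.05
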