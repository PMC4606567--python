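"""Nomenclature, registry fidelity, formula rules, enumeration, standards."""

import itertools

import pytest

from lipidshot.chem_core import adduct_mz, monoisotopic_mass, parse_formula
from lipidshot.lipid_model import (
    ChainBounds,
    MolecularSpeciesAnnotation,
    SpeciesAnnotation,
    build_default_registry,
    candidate_chain_pairs,
    default_ranges,
    default_standards,
    enumerate_species,
    parse_species_name,
    species_formula,
    standard_for_class,
    write_species_name,
)

# (class, polarity, adduct, identification mode, structural level) for all
# 22 default classes; the panel's acquisition/identification strategy.
EXPECTED_REGISTRY = {
    "Cer": ("negative", "plus-OAc", "MS-only", "species"),
    "Chol": ("positive", "plus-NH4", "MS-only", "species"),
    "DAG": ("positive", "plus-NH4", "MS-plus-MSMS", "molecular-species"),
    "HexCer": ("negative", "plus-OAc", "MS-only", "species"),
    "LPA": ("negative", "minus-H", "MS-only", "molecular-species"),
    "LPC": ("negative", "plus-OAc", "MS-only", "molecular-species"),
    "LPC O-": ("negative", "plus-OAc", "MS-only", "molecular-species"),
    "LPE": ("negative", "minus-H", "MS-only", "molecular-species"),
    "LPE O-": ("negative", "minus-H", "MS-only", "molecular-species"),
    "LPI": ("negative", "minus-H", "MS-only", "molecular-species"),
    "LPS": ("negative", "minus-H", "MS-only", "molecular-species"),
    "PA": ("negative", "minus-H", "MS-plus-MSMS", "molecular-species"),
    "PC": ("negative", "plus-OAc", "MS-plus-MSMS", "molecular-species"),
    "PC O-": ("negative", "plus-OAc", "MS-only", "species"),
    "PE": ("negative", "minus-H", "MS-plus-MSMS", "molecular-species"),
    "PE O-": ("negative", "minus-H", "MS-only", "species"),
    "PG": ("negative", "minus-H", "MS-plus-MSMS", "molecular-species"),
    "PI": ("negative", "minus-H", "MS-plus-MSMS", "molecular-species"),
    "PS": ("negative", "minus-H", "MS-plus-MSMS", "molecular-species"),
    "CE": ("positive", "plus-NH4", "MS-plus-MSMS", "molecular-species"),
    "SM": ("negative", "plus-OAc", "MS-only", "species"),
    "TAG": ("positive", "plus-NH4", "MS-plus-MSMS", "species"),
}


class TestParseName:
    def test_sphingomyelin_standard(self):
        a = parse_species_name("SM 18:1;2/12:0")
        assert isinstance(a, MolecularSpeciesAnnotation)
        assert a.chains == ((18, 1, 2), (12, 0, 0))

    def test_triacylglycerol_standard(self):
        a = parse_species_name("TAG 17:0/17:0/17:0")
        assert isinstance(a, MolecularSpeciesAnnotation)
        assert len(a.chains) == 3

    def test_ether_species(self):
        a = parse_species_name("PC O-34:1")
        assert isinstance(a, SpeciesAnnotation)
        assert a.ether and (a.total_c, a.total_db, a.total_oh) == (34, 1, 0)

    def test_chainless_class(self):
        a = parse_species_name("Chol")
        assert (a.total_c, a.total_db, a.total_oh) == (0, 0, 0)

    @pytest.mark.parametrize("bad", ["PC 34;1", "PC 1:2:3", "PC 10:12"])
    def test_malformed_names(self, bad):
        with pytest.raises(ValueError):
            parse_species_name(bad)

    def test_roundtrip_standard_mixture_names(self):
        names = [
            "LPG 17:1", "LPA 17:0", "PC 17:0/17:0", "HexCer 18:1;2/12:0",
            "PS 17:0/17:0", "PG 17:0/17:0", "PA 17:0/17:0", "LPI 17:1",
            "LPS 17:1", "DAG 17:0/17:0", "TAG 17:0/17:0/17:0",
            "Cer 18:1;2/17:0", "SM 18:1;2/12:0", "LPC 12:0", "LPE 17:1",
            "PE 17:0/17:0", "CE 20:0", "PI 16:0/16:0", "PC O-34:1",
            "LPC O-18:1",
        ]
        for name in names:
            assert write_species_name(parse_species_name(name)) == name


class TestRegistry:
    def test_exactly_22_classes(self, registry):
        assert len(registry) == 22

    def test_modes_levels_polarities_adducts(self, registry):
        got = {
            c.class_name: (c.polarity, c.adduct.name, c.identification_mode,
                           c.structural_level)
            for c in registry
        }
        assert got == EXPECTED_REGISTRY

    def test_optional_lpg_class(self):
        reg = build_default_registry(include_lpg=True)
        assert len(reg) == 23 and "LPG" in reg

    def test_deconvolution_channels_only_on_molecular_classes(self, registry):
        for cdef in registry:
            for rule in cdef.fragment_rules:
                if rule.has_role("deconvolution-channel"):
                    assert cdef.structural_level == "molecular-species"


class TestSpeciesFormula:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("PC 34:1", "C42H82NO8P"),
            ("PC 16:0/18:1", "C42H82NO8P"),
            ("PE 34:1", "C39H76NO8P"),
            ("PS 34:1", "C40H76NO10P"),
            ("PG 34:1", "C40H77O10P"),
            ("PI 34:1", "C43H81O13P"),
            ("PA 34:1", "C37H71O8P"),
            ("PC O-34:1", "C42H84NO7P"),
            ("LPC 12:0", "C20H42NO7P"),
            ("LPC O-18:1", "C26H54NO6P"),
            ("SM 18:1;2/12:0", "C35H71N2O6P"),
            ("Cer 18:1;2/17:0", "C35H69NO3"),
            ("HexCer 18:1;2/12:0", "C36H69NO8"),
            ("Chol", "C27H46O"),
            ("CE 16:0", "C43H76O2"),
            ("DAG 16:0/18:1", "C37H70O5"),
            ("TAG 16:0/18:1/18:1", "C55H102O6"),
        ],
    )
    def test_reference_formulas(self, registry, name, expected):
        f = species_formula(parse_species_name(name), registry)
        assert str(f) == expected

    def test_pc341_reference_mass(self, registry):
        f = species_formula(parse_species_name("PC 34:1"), registry)
        assert monoisotopic_mass(f) == pytest.approx(759.5778, abs=5e-4)

    def test_molecular_equals_sum_composition(self, registry):
        for name in ["PC 16:0/18:1", "PE 17:0/17:0", "TAG 16:0/18:1/18:1",
                     "SM 18:1;2/12:0"]:
            mol = parse_species_name(name)
            assert species_formula(mol, registry) == species_formula(
                mol.sum_composition(), registry
            )

    def test_arity_mismatch_rejected(self, registry):
        with pytest.raises(ValueError):
            species_formula(
                MolecularSpeciesAnnotation("TAG", ((16, 0, 0), (18, 1, 0))),
                registry,
            )


class TestEnumeration:
    def test_range_arithmetic_single_class(self, registry):
        from lipidshot.lipid_model import ClassRanges

        entries = enumerate_species(registry, {"PC": ClassRanges(34, 34, 0, 2)})
        assert len(entries) == 3

    def test_default_breadth(self, registry):
        entries = enumerate_species(registry)
        assert len(entries) >= 200
        keys = {
            (e.annotation.class_name, e.annotation.total_c,
             e.annotation.total_db, e.annotation.total_oh)
            for e in entries
        }
        assert len(keys) == len(entries)  # duplicate-free
        assert {e.annotation.class_name for e in entries} == set(
            EXPECTED_REGISTRY
        )

    def test_mz_consistent_with_adduct(self, registry):
        for e in enumerate_species(registry)[::97]:
            assert e.mz == pytest.approx(
                adduct_mz(e.formula, e.class_def.adduct), abs=1e-12
            )


class TestStandards:
    def test_nineteen_components(self, standards):
        assert len(standards) == 19

    @pytest.mark.parametrize(
        "cls,amount",
        [("PC", 500), ("Chol", 1000), ("SM", 200), ("Cer", 50),
         ("HexCer", 30), ("LPE", 30), ("DAG", 100), ("CE", 100), ("TAG", 50)],
    )
    def test_amounts(self, standards, cls, amount):
        std = standard_for_class(cls, standards)
        assert std is not None and std.amount_pmol == amount

    def test_one_standard_per_class(self, standards):
        classes = [s.class_name for s in standards]
        assert len(classes) == len(set(classes))

    def test_labeled_cholesterol_override(self, standards, registry):
        std = standard_for_class("Chol", standards)
        assert std.label == "Chol D6"
        assert str(std.neutral_formula(registry)) == "C27H40D6O"
        # six mass units heavier than endogenous cholesterol, minus the
        # proton-neutron difference per substitution
        d = monoisotopic_mass(std.neutral_formula(registry)) - monoisotopic_mass(
            parse_formula("C27H46O")
        )
        assert d == pytest.approx(6 * 1.00628, abs=1e-4)

    def test_ether_classes_borrow_diacyl_standard(self, standards):
        assert standard_for_class("PC O-", standards).class_name == "PC"
        assert standard_for_class("LPE O-", standards).class_name == "LPE"


class TestCandidateChainPairs:
    def test_unique_decomposition(self, registry):
        s = SpeciesAnnotation("PC", 34, 1)
        cands = candidate_chain_pairs(s, registry, ChainBounds(16, 18, 0, 1))
        assert {c.chains for c in cands} == {
            ((18, 1, 0), (16, 0, 0)),
            ((17, 1, 0), (17, 0, 0)),
            ((18, 0, 0), (16, 1, 0)),
        }

    def test_matches_brute_force_grid(self, registry):
        s = SpeciesAnnotation("PC", 34, 1)
        b = ChainBounds(14, 20, 0, 1)
        cands = {c.chains for c in candidate_chain_pairs(s, registry, b)}
        brute = set()
        for c1, d1 in itertools.product(range(14, 21), range(0, 2)):
            c2, d2 = 34 - c1, 1 - d1
            if 14 <= c2 <= 20 and 0 <= d2 <= 1:
                from lipidshot.lipid_model import canonical_chain_order

                brute.add(canonical_chain_order([(c1, d1, 0), (c2, d2, 0)]))
        assert cands == brute
        assert ((16, 0, 0), (18, 1, 0)) in {tuple(sorted(c)) for c in cands}

    def test_lyso_single_chain(self, registry):
        s = SpeciesAnnotation("LPC", 18, 1)
        cands = candidate_chain_pairs(s, registry)
        assert len(cands) == 1 and cands[0].chains == ((18, 1, 0),)

    def test_species_level_class_rejected(self, registry):
        with pytest.raises(ValueError):
            candidate_chain_pairs(SpeciesAnnotation("SM", 34, 1, 2), registry)

    def test_sums_preserved(self, registry):
        s = SpeciesAnnotation("DAG", 34, 2)
        cands = candidate_chain_pairs(s, registry, ChainBounds(14, 20, 0, 2))
        assert cands
        for cand in cands:
            assert cand.total_c == 34 and cand.total_db == 2
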