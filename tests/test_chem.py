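"""Composition algebra: parsing, masses, formulas, isotopic envelopes,
structure classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nglyco.chem import (CompositionParseError, ElementCounts, GlycanComposition,
                         SialylationWarning, StructureError, classify_structure,
                         enumerate_compositions, isotopic_distribution,
                         isotopic_distribution_enumerated, min_isotopologues,
                         molecular_formula, monoisotopic_mass, parse_composition)

WATER_MASS = 18.0105646863


@pytest.mark.parametrize("code, expected", [
    ("H5N4E2", (5, 4, 0, 0, 2)),
    ("H5N4F1L1E1", (5, 4, 1, 1, 1)),
    ("H3N2", (3, 2, 0, 0, 0)),
    ("N4H5", (5, 4, 0, 0, 0)),          # order-insensitive input
])
def test_parse_composition(code, expected):
    comp = parse_composition(code)
    assert (comp.h, comp.n, comp.f, comp.l, comp.e) == expected


@pytest.mark.parametrize("code, fragment", [
    ("H5X2", "X"),            # unknown letter
    ("H5N4N2", "duplicate"),  # duplicated letter
    ("", "empty"),
    ("H5N", "malformed"),
])
def test_parse_composition_errors(code, fragment):
    with pytest.raises(CompositionParseError, match=fragment):
        parse_composition(code)


@given(st.builds(GlycanComposition,
                 h=st.integers(0, 9), n=st.integers(0, 7), f=st.integers(0, 3),
                 l=st.integers(0, 4), e=st.integers(0, 4)))
@settings(max_examples=50, deadline=None)
def test_code_round_trip_is_canonical(comp):
    if comp.code:
        assert parse_composition(comp.code) == comp


def test_monoisotopic_mass_examples():
    h3n2 = parse_composition("H3N2")
    assert monoisotopic_mass(h3n2, "neutral") == pytest.approx(910.3278, abs=5e-4)
    delta = monoisotopic_mass(h3n2, "sodiated") - monoisotopic_mass(h3n2, "neutral")
    assert delta == pytest.approx(22.9892, abs=5e-4)
    assert monoisotopic_mass(GlycanComposition(), "neutral") == pytest.approx(
        WATER_MASS, abs=5e-4)
    with pytest.raises(ValueError):
        monoisotopic_mass(h3n2, "protonated")


def test_molecular_formula_examples():
    assert molecular_formula(parse_composition("H3N2")).formula() == "C34H58N2O26"
    assert molecular_formula(GlycanComposition()).formula() == "H2O"
    # ethyl ester (+C2H4) vs lactone (-H2O) on the same sialic acid parent
    e1 = molecular_formula(GlycanComposition(e=1))
    l1 = molecular_formula(GlycanComposition(l=1))
    assert (e1.c - l1.c, e1.h - l1.h, e1.n - l1.n, e1.o - l1.o) == (2, 6, 0, 1)


def test_mass_matches_independent_atom_sum_oracle(registry):
    """Neutral masses agree with pyteomics' atom-sum calculator to 1e-4 Da."""
    from pyteomics.mass import calculate_mass

    for rec in registry:
        f = molecular_formula(rec.composition)
        oracle = calculate_mass(composition={"C": f.c, "H": f.h,
                                             "N": f.n, "O": f.o})
        assert rec.mass_neutral == pytest.approx(oracle, abs=1e-4), rec.code
        assert rec.mass_sodiated - rec.mass_neutral == pytest.approx(
            22.9892, abs=5e-4)


def test_formula_mass_consistency(registry):
    for rec in registry:
        assert molecular_formula(rec.composition).mass() == pytest.approx(
            monoisotopic_mass(rec.composition, "neutral"), abs=1e-6)


@given(st.tuples(*[st.integers(0, 5)] * 5), st.tuples(*[st.integers(0, 5)] * 5))
@settings(max_examples=50, deadline=None)
def test_mass_additivity_under_merging(a, b):
    """mass(c1 merged c2) = mass(c1) + mass(c2) - mass(H2O)."""
    c1, c2 = GlycanComposition(*a), GlycanComposition(*b)
    merged = monoisotopic_mass(c1.merge(c2), "neutral")
    assert merged == pytest.approx(
        monoisotopic_mass(c1, "neutral") + monoisotopic_mass(c2, "neutral")
        - molecular_formula(GlycanComposition()).mass(), abs=1e-9)


class TestIsotopicDistribution:
    def test_k1_is_unity(self):
        f = molecular_formula(parse_composition("H5N4E2"))
        assert isotopic_distribution(f, 1).tolist() == [1.0]

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            isotopic_distribution(ElementCounts(2, 2, 0, 0), 0)

    def test_m1_over_m0_ratio(self):
        """M+1/M+0 of C34H58N2O26 equals the heavy-isotope probability sum."""
        d = isotopic_distribution(molecular_formula(parse_composition("H3N2")), 3)
        assert d[1] / d[0] == pytest.approx(0.388, abs=0.01)

    @pytest.mark.parametrize("formula", [
        ElementCounts(2, 2, 0, 0),        # C2H2
        ElementCounts(1, 2, 0, 1),        # CH2O
        ElementCounts(0, 2, 1, 2),
        ElementCounts(3, 1, 1, 1),
    ])
    def test_matches_exhaustive_enumeration(self, formula):
        for k in (1, 2, 4):
            conv = isotopic_distribution(formula, k)
            enum = isotopic_distribution_enumerated(formula, k)
            assert np.max(np.abs(conv - enum)) < 1e-12

    def test_nonnegative_and_normalized(self, registry):
        for rec in registry:
            f = molecular_formula(rec.composition)
            k = min_isotopologues(f)
            d = isotopic_distribution(f, k)
            assert (d >= 0).all()
            assert d.sum() == pytest.approx(1.0, abs=1e-12)
            # 95% coverage definition: raw envelope mass up to k reaches 0.95
            assert k >= 1


class TestClassifyStructure:
    def test_high_mannose(self):
        ft = classify_structure(parse_composition("H5N2"))
        assert ft.glycan_class == "high-mannose"
        assert ft.antennae is None and not ft.fucosylated

    def test_diantennary_disialylated(self):
        ft = classify_structure(parse_composition("H5N4E2"))
        assert (ft.glycan_class, ft.antennae, ft.galactoses) == ("complex", 2, 2)
        assert ft.sialic_total == 2 and not ft.fucosylated

    def test_triantennary_fucosylated(self):
        ft = classify_structure(parse_composition("H6N5F1L1"))
        assert (ft.glycan_class, ft.antennae, ft.galactoses) == ("complex", 3, 3)
        assert ft.sialic_total == 1 and ft.fucosylated

    def test_hybrid_rule(self):
        assert classify_structure(parse_composition("H5N3")).glycan_class == "hybrid"
        assert classify_structure(parse_composition("H6N3E1")).glycan_class == "hybrid"

    def test_bisection_annotation_shifts_antennae(self):
        plain = classify_structure(parse_composition("H5N5"))
        bis = classify_structure(parse_composition("H5N5"), bisected=True)
        assert plain.antennae == 3 and bis.antennae == 2 and bis.bisected

    def test_core_constraint_errors(self):
        with pytest.raises(StructureError):
            classify_structure(GlycanComposition(h=2, n=2))
        with pytest.raises(StructureError):
            classify_structure(GlycanComposition(h=5, n=1))
        with pytest.raises(StructureError):       # n=2 with fucose: 0 antennae
            classify_structure(parse_composition("H3N2F1"))

    def test_excess_sialylation_warns_but_retains_counts(self):
        with pytest.warns(SialylationWarning):
            ft = classify_structure(parse_composition("H3N4E2"))
        assert ft.sialic_total == 2 and ft.galactoses == 0

    def test_galactoses_never_exceed_antennae(self):
        for comp in enumerate_compositions():
            ft = classify_structure(comp)
            if ft.glycan_class == "complex":
                assert 0 <= ft.galactoses <= ft.antennae
                assert 2 <= ft.antennae <= 4
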