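"""Unit and property tests for formula arithmetic, ions and isotope patterns."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cimion.chem_core import (
    ELECTRON_MASS,
    ION_SPECIES,
    ISOTOPES,
    DerivatizedCompound,
    ElementalFormula,
    IsotopePattern,
    UnsupportedElementError,
    derivatize,
    ion_mz,
    isotope_pattern,
    monoisotopic_mass,
)

from conftest import TABLE4


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration over isotopologue combinations
# ---------------------------------------------------------------------------

def _compositions(n, k):
    """All ways to split n atoms over k isotope slots."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def oracle_isotope_pattern(formula: ElementalFormula, max_shift: int):
    """Brute-force isotopologue enumeration, aggregated on nominal shift."""
    bins = {}  # shift -> [abundance, weighted mass]
    per_element = []
    for el, n in formula.counts.items():
        iso = ISOTOPES[el]
        base_nominal = round(iso[0][0])
        options = []
        for comp in _compositions(n, len(iso)):
            multinom = math.factorial(n)
            prob = 1.0
            mass = 0.0
            shift = 0
            for count, (imass, iab) in zip(comp, iso):
                multinom //= math.factorial(count)
                prob *= iab ** count
                mass += count * imass
                shift += count * (round(imass) - base_nominal)
            options.append((shift, mass, multinom * prob))
        per_element.append(options)
    for combo in itertools.product(*per_element):
        shift = sum(c[0] for c in combo)
        if shift > max_shift:
            continue
        mass = sum(c[1] for c in combo)
        prob = math.prod(c[2] for c in combo)
        entry = bins.setdefault(shift, [0.0, 0.0])
        entry[0] += prob
        entry[1] += prob * mass
    total = sum(a for a, _ in bins.values())
    return {s: (wm / a, a / total) for s, (a, wm) in sorted(bins.items())}


# ---------------------------------------------------------------------------
# ElementalFormula
# ---------------------------------------------------------------------------

class TestElementalFormula:
    def test_parse_hill_round_trip(self):
        f = ElementalFormula.parse("C17H32O4Si3")
        assert f.counts == {"C": 17, "H": 32, "O": 4, "Si": 3}
        assert f.hill() == "C17H32O4Si3"

    @pytest.mark.parametrize("text", ["H3PO4", "CH4", "C6H12O6", "Si3C9H27O4P"])
    def test_round_trip_stable(self, text):
        f = ElementalFormula.parse(text)
        assert ElementalFormula.parse(f.hill()).counts == f.counts

    def test_addition_elementwise(self):
        a = ElementalFormula.parse("C2H6O") + ElementalFormula.parse("CH2")
        assert a.counts == {"C": 3, "H": 8, "O": 1}

    def test_subtraction_never_negative(self):
        with pytest.raises(ValueError, match="negative"):
            ElementalFormula.parse("CH4") - ElementalFormula.parse("C2H2")

    def test_unsupported_element_named(self):
        with pytest.raises(UnsupportedElementError, match="Fe"):
            ElementalFormula.parse("FeO")
        with pytest.raises(UnsupportedElementError, match="Na"):
            ElementalFormula({"Na": 1})

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ElementalFormula({"C": -1})

    def test_empty_formula_mass_zero(self):
        assert monoisotopic_mass(ElementalFormula()) == 0.0


# ---------------------------------------------------------------------------
# monoisotopic_mass / derivatize / ion_mz
# ---------------------------------------------------------------------------

class TestMasses:
    def test_dopac_3tms(self):
        f = ElementalFormula.parse("C17H32O4Si3")
        assert monoisotopic_mass(f) == pytest.approx(384.1608, abs=1e-4)

    def test_phosphoric_mh(self):
        f = ElementalFormula.parse("C9H27O4PSi3") + ElementalFormula.parse("H")
        assert monoisotopic_mass(f) == pytest.approx(315.1033, abs=1e-4)

    def test_deterministic(self):
        f = ElementalFormula.parse("C10H20N2O5S")
        assert monoisotopic_mass(f) == monoisotopic_mass(f)


class TestDerivatize:
    def test_dopac_three_tms(self):
        base = ElementalFormula.parse("C8H8O4")
        assert derivatize(base, 3).hill() == "C17H32O4Si3"

    def test_identity(self):
        base = ElementalFormula.parse("C6H12O6")
        assert derivatize(base, 0, 0).counts == base.counts

    def test_phosphoric(self):
        d = derivatize(ElementalFormula.parse("H3PO4"), 3)
        assert d.hill() == "C9H27O4PSi3"
        assert monoisotopic_mass(d) == pytest.approx(314.0955, abs=1e-4)

    def test_mass_shifts(self):
        base = ElementalFormula.parse("C6H12O6")
        m0 = monoisotopic_mass(base)
        assert monoisotopic_mass(derivatize(base, 1)) - m0 == pytest.approx(72.0395, abs=5e-4)
        assert monoisotopic_mass(derivatize(base, 0, 1)) - m0 == pytest.approx(29.0266, abs=5e-4)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            derivatize(ElementalFormula.parse("C6H12O6"), -1)

    def test_insufficient_hydrogens_error(self):
        with pytest.raises(ValueError, match="hydrogens"):
            derivatize(ElementalFormula.parse("H3PO4"), 4)

    @given(a=st.integers(0, 4), b=st.integers(0, 4))
    def test_additive(self, a, b):
        base = ElementalFormula.parse("C6H12O6")
        lhs = derivatize(base, a + b)
        rhs = derivatize(derivatize(base, a), b)
        assert lhs.counts == rhs.counts


class TestIonMz:
    @pytest.mark.parametrize("compound", TABLE4)
    def test_table4_theoretical_values(self, compound):
        entry = TABLE4[compound]
        neutral = derivatize(ElementalFormula.parse(entry["base_formula"]), entry["n_tms"])
        assert neutral.hill() == entry["derivatized"]
        for _, theoretical, _, label in entry["rows"]:
            assert ion_mz(neutral, ION_SPECIES[label]) == pytest.approx(theoretical, abs=1e-4)

    def test_inapplicable_delta_errors(self):
        water = ElementalFormula.parse("H2O")
        with pytest.raises(ValueError, match="not applicable"):
            ion_mz(water, ION_SPECIES["[M-CH3]+"])

    def test_electron_correction_flag(self):
        f = ElementalFormula.parse("C17H32O4Si3")
        plain = ion_mz(f, ION_SPECIES["[M]+"])
        corrected = ion_mz(f, ION_SPECIES["[M]+"], electron_correction=True)
        assert plain - corrected == pytest.approx(ELECTRON_MASS, abs=1e-9)

    def test_label_delta_bijection(self):
        deltas = {sp.delta_mass for sp in ION_SPECIES.values()}
        assert len(deltas) == len(ION_SPECIES)


_random_formula = st.builds(
    ElementalFormula,
    st.fixed_dictionaries(
        {
            "C": st.integers(1, 40),
            "H": st.integers(3, 80),
            "N": st.integers(0, 6),
            "O": st.integers(0, 15),
            "P": st.integers(0, 2),
            "S": st.integers(0, 2),
            "Si": st.integers(0, 8),
        }
    ),
)


class TestSpeciesDeltaInvariants:
    @settings(max_examples=200, deadline=None)
    @given(f=_random_formula)
    def test_pairwise_deltas(self, f):
        labels = ("[M-H]+", "[M]+", "[M+H]+", "[M-CH3]+", "[M+C2H5]+", "[M+C3H5]+", "[M+TMS]+")
        mz = {label: ion_mz(f, ION_SPECIES[label]) for label in labels}
        assert mz["[M+H]+"] - mz["[M-H]+"] == pytest.approx(2.015650, abs=1e-5)
        assert mz["[M]+"] - mz["[M-CH3]+"] == pytest.approx(15.023475, abs=1e-5)
        assert mz["[M+TMS]+"] - mz["[M]+"] == pytest.approx(73.047352, abs=1e-5)
        assert mz["[M+C3H5]+"] - mz["[M+C2H5]+"] == pytest.approx(12.0, abs=1e-9)


# ---------------------------------------------------------------------------
# isotope patterns
# ---------------------------------------------------------------------------

class TestIsotopePattern:
    def test_single_carbon(self):
        pat = isotope_pattern(ElementalFormula.parse("C"), 1)
        assert pat.abundances[0] == pytest.approx(0.9893, abs=1e-4)
        assert pat.abundances[1] == pytest.approx(0.0107, abs=1e-4)

    def test_water_truncated_to_single_peak(self):
        pat = isotope_pattern(ElementalFormula.parse("H2O"), 0)
        assert len(pat.peaks) == 1
        assert pat.abundances[0] == pytest.approx(1.0, abs=1e-12)

    def test_negative_shift_rejected(self):
        with pytest.raises(ValueError):
            isotope_pattern(ElementalFormula.parse("CH4"), -1)

    # expected A+1/A ratio frozen from the exhaustive enumeration oracle
    def test_dopac_a1_ratio_frozen(self):
        pat = isotope_pattern(ElementalFormula.parse("C17H32O4Si3"), 2)
        assert pat.ratio(1) == pytest.approx(0.3414738, abs=1e-4)

    @pytest.mark.parametrize(
        "text", ["CH4", "H2O", "C2H5NO2", "C3H9Si", "SiO2", "H3PO4", "C2H6S"]
    )
    def test_matches_exhaustive_oracle(self, text):
        f = ElementalFormula.parse(text)
        assert f.n_atoms <= 30
        pat = isotope_pattern(f, 3)
        oracle = oracle_isotope_pattern(f, 3)
        assert len(pat.peaks) == len(oracle)
        for (mass, ab), (shift, (omass, oab)) in zip(pat.peaks, oracle.items()):
            assert ab == pytest.approx(oab, abs=1e-6)
            assert mass == pytest.approx(omass, abs=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(
        f=st.builds(
            ElementalFormula,
            st.fixed_dictionaries(
                {
                    "C": st.integers(0, 30),
                    "H": st.integers(0, 60),
                    "O": st.integers(0, 10),
                    "Si": st.integers(0, 6),
                }
            ),
        ),
        max_shift=st.integers(0, 4),
    )
    def test_abundances_sum_to_one(self, f, max_shift):
        if not f:
            return
        pat = isotope_pattern(f, max_shift)
        assert sum(pat.abundances) == pytest.approx(1.0, abs=1e-9)
        masses = pat.masses
        assert all(b > a for a, b in zip(masses, masses[1:]))


# ---------------------------------------------------------------------------
# DerivatizedCompound
# ---------------------------------------------------------------------------

class TestDerivatizedCompound:
    def test_mass_increases_with_derivatization(self):
        c = DerivatizedCompound("glucose", ElementalFormula.parse("C6H12O6"), 5, 1)
        assert c.neutral_mass > monoisotopic_mass(c.base_formula)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            DerivatizedCompound("x", ElementalFormula.parse("CH4"), -1)
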