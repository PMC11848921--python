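"""Mass arithmetic: compositions, residue tables, envelopes, adducts.

The residue compositions are validated against an independent fragment-wise
atom count of the aeg-PNA structure: the N-(2-aminoethyl)glycine backbone
residue (-NH-CH2-CH2-N<-CH2-CO-), the acetyl linker to the nucleobase
(-CO-CH2-), and the nucleobase radical attached through its glycosylation
nitrogen.
"""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from pnaseq.chem import (
    ADDUCT_OFFSETS,
    DEFAULT_REGISTRY,
    ElementalComposition,
    OligomerSpecies,
    TerminusState,
    adduct_mz,
    compose_oligomer,
    isotope_envelope,
    monoisotopic_mass,
    terminator_delta,
)
from pnaseq.elements import ISOTOPES
from pnaseq.errors import ConfigurationError, DomainError

# ---------------------------------------------------------------------------
# Independent atom-count oracle: fragments of the drawn aeg-PNA residue
# ---------------------------------------------------------------------------

BACKBONE = {"C": 4, "H": 7, "N": 2, "O": 1}   # -NH-CH2-CH2-N<-CH2-C(=O)-
LINKER = {"C": 2, "H": 2, "O": 1}             # -C(=O)-CH2- to the base
BASE_RADICALS = {
    "A": {"C": 5, "H": 4, "N": 5},            # adenin-9-yl
    "C": {"C": 4, "H": 4, "N": 3, "O": 1},    # cytosin-1-yl
    "G": {"C": 5, "H": 4, "N": 5, "O": 1},    # guanin-9-yl
    "T": {"C": 5, "H": 5, "N": 2, "O": 2},    # thymin-1-yl
}


def oracle_residue_composition(base):
    counts = {}
    for frag in (BACKBONE, LINKER, BASE_RADICALS[base]):
        for el, n in frag.items():
            counts[el] = counts.get(el, 0) + n
    return ElementalComposition.from_counts(counts)


@pytest.mark.parametrize("base", "ACGT")
def test_residue_composition_matches_structural_atom_count(base):
    assert DEFAULT_REGISTRY.residue(base).composition == \
        oracle_residue_composition(base)


def test_residue_masses_match_atom_count_oracle():
    # one oligomer per base, against a mass summed from the oracle counts
    for base in "ACGT":
        species = OligomerSpecies(base, TerminusState("free-amine", "free-acid"))
        oracle = monoisotopic_mass(oracle_residue_composition(base)) + \
            monoisotopic_mass(ElementalComposition.from_formula("H2O"))
        assert species.mass() == pytest.approx(oracle, abs=1e-9)


# ---------------------------------------------------------------------------
# Composition arithmetic
# ---------------------------------------------------------------------------

def test_composition_arithmetic_exact():
    a = ElementalComposition.from_formula("C2H6O")
    b = ElementalComposition.from_formula("H2O")
    assert (a + b).counts == {"C": 2, "H": 8, "O": 2}
    assert (a - b).counts == {"C": 2, "H": 4}
    assert (2 * b).counts == {"H": 4, "O": 2}
    with pytest.raises(DomainError):
        b - a  # would go negative in C
    with pytest.raises(DomainError):
        ElementalComposition.from_counts({"C": -1})
    with pytest.raises(DomainError):
        ElementalComposition.from_formula("C2x")


@given(
    st.dictionaries(st.sampled_from("CHNOS"), st.integers(0, 50), max_size=5),
    st.dictionaries(st.sampled_from("CHNOS"), st.integers(0, 50), max_size=5),
)
@settings(derandomize=True, max_examples=50)
def test_mass_is_linear(c1, c2):
    a = ElementalComposition.from_counts(c1)
    b = ElementalComposition.from_counts(c2)
    assert monoisotopic_mass(a + b) == pytest.approx(
        monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-9
    )


def test_water_mass():
    assert monoisotopic_mass(ElementalComposition.from_formula("H2O")) == \
        pytest.approx(18.0106, abs=0.0005)
    assert monoisotopic_mass(ElementalComposition()) == 0.0


# ---------------------------------------------------------------------------
# Oligomer composition
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("termini", [
    TerminusState("free-amine", "amide"),
    TerminusState("azide", "free-acid"),
    TerminusState("acetyl", "linker-biotin"),
])
def test_compose_is_additive_in_residues(termini):
    for x, y in itertools.product("ACGT", repeat=2):
        m_xy = monoisotopic_mass(compose_oligomer(x + y, termini))
        m_x = monoisotopic_mass(compose_oligomer(x, termini))
        assert m_xy - m_x == pytest.approx(
            DEFAULT_REGISTRY.residue_mass(y), abs=1e-9
        )


def test_single_T_free_acid_is_residue_plus_water():
    comp = compose_oligomer("T", TerminusState("free-amine", "free-acid"))
    expected = DEFAULT_REGISTRY.residue("T").composition + \
        ElementalComposition.from_formula("H2O")
    assert comp == expected


def test_oxidation_adds_one_oxygen():
    t = TerminusState("free-amine", "amide")
    d = monoisotopic_mass(compose_oligomer("A", t, oxidations=1)) - \
        monoisotopic_mass(compose_oligomer("A", t))
    assert d == pytest.approx(15.9949, abs=1e-4)


def test_compose_rejects_bad_input():
    t = TerminusState()
    with pytest.raises(DomainError):
        compose_oligomer("", t)
    with pytest.raises(ConfigurationError):
        compose_oligomer("AXZ", t)
    with pytest.raises(ConfigurationError):
        compose_oligomer("A", TerminusState("nonsense", "amide"))


def test_serine_modified_residues_add_CH2O():
    ch2o = ElementalComposition.from_formula("CH2O")
    for b in "ACGT":
        assert DEFAULT_REGISTRY.residue(b.lower()).composition == \
            DEFAULT_REGISTRY.residue(b).composition + ch2o


# ---------------------------------------------------------------------------
# Ladder discriminability and the designed G vs A+O confound
# ---------------------------------------------------------------------------

def test_residue_mass_gaps_exceed_8_Da():
    masses = sorted(DEFAULT_REGISTRY.aeg_masses().values())
    for a, b in itertools.combinations(masses, 2):
        assert abs(a - b) > 8.0


def test_G_equals_A_plus_oxygen_exactly():
    a = DEFAULT_REGISTRY.residue("A").composition
    g = DEFAULT_REGISTRY.residue("G").composition
    assert g == a + ElementalComposition.from_formula("O")


# ---------------------------------------------------------------------------
# Isotope envelopes vs exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_envelope_oracle(composition):
    """Brute-force isotopologue enumeration, grouped by nucleon offset."""
    atoms = []
    for el, n in composition.counts.items():
        atoms.extend([el] * n)
    groups = {}
    for combo in itertools.product(*[ISOTOPES[el] for el in atoms]):
        mass = sum(m for m, _ in combo)
        prob = math.prod(a for _, a in combo)
        mono = sum(ISOTOPES[el][0][0] for el in atoms)
        k = round(mass - mono)
        p, mo = groups.get(k, (0.0, 0.0))
        groups[k] = (p + prob, mo + prob * (mass - mono))
    return {k: (p, mo / p) for k, (p, mo) in groups.items() if p > 0}


@pytest.mark.parametrize("formula", ["H2O", "CH4", "C2H5NOS", "K2S", "C2H4O2"])
def test_envelope_matches_enumeration_oracle(formula):
    comp = ElementalComposition.from_formula(formula)
    assert comp.total_atoms() <= 10
    oracle = enumerate_envelope_oracle(comp)
    env = isotope_envelope(comp, max_peaks=12)
    for k, (offset, abundance) in enumerate(env):
        if k in oracle:
            assert abundance == pytest.approx(oracle[k][0], abs=1e-9)
            if oracle[k][0] > 1e-9:  # centroids of vanishing peaks are moot
                assert offset == pytest.approx(oracle[k][1], abs=1e-9)
        else:
            assert abundance < 1e-9


def test_envelope_single_carbon():
    env = isotope_envelope(ElementalComposition.from_formula("C"), 5)
    assert env[0] == pytest.approx((0.0, 0.9893))
    assert env[1][0] == pytest.approx(1.00336, abs=1e-4)
    assert env[1][1] == pytest.approx(0.0107)


def test_envelope_empty_composition():
    assert isotope_envelope(ElementalComposition(), 5) == [(0.0, 1.0)]


def test_envelope_normalized_and_sorted():
    comp = ElementalComposition.from_formula("C100H150N40O30S2")
    env = isotope_envelope(comp, max_peaks=60)
    assert sum(a for _, a in env) == pytest.approx(1.0, abs=1e-9)
    offsets = [o for o, _ in env]
    assert offsets == sorted(offsets)
    # ~1.003 Da spacing for C-dominated species
    assert env[1][0] - env[0][0] == pytest.approx(1.003, abs=0.01)


def test_envelope_rejects_bad_max_peaks():
    with pytest.raises(DomainError):
        isotope_envelope(ElementalComposition.from_formula("C"), 0)


# ---------------------------------------------------------------------------
# Adducts and the reversible terminator
# ---------------------------------------------------------------------------

def test_adduct_offsets():
    m = 1234.5
    assert adduct_mz(m, "M+Na") - adduct_mz(m, "M+H") == \
        pytest.approx(21.9819, abs=0.001)
    assert adduct_mz(m, "M+K") - adduct_mz(m, "M+H") == \
        pytest.approx(37.9559, abs=0.001)
    assert adduct_mz(m, "M+H") == pytest.approx(m + 1.00728, abs=0.0001)
    with pytest.raises(DomainError):
        adduct_mz(0.0, "M+H")
    with pytest.raises(DomainError):
        adduct_mz(m, "M+Cs")


def test_terminator_delta_value_and_consistency():
    assert terminator_delta() == pytest.approx(-25.9905, abs=0.001)
    azide = OligomerSpecies("ACGT", TerminusState("azide", "amide"))
    amine = azide.reduced()
    assert amine.termini.n_terminus == "free-amine"
    assert azide.mass() - amine.mass() == pytest.approx(-terminator_delta(), abs=1e-9)
    # reducing an already-reduced species changes nothing
    assert amine.reduced() is amine


def test_adduct_table_is_consistent_with_elements():
    assert ADDUCT_OFFSETS["M+H"] == pytest.approx(1.007276, abs=1e-5)
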