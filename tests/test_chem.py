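"""Formula parsing, monoisotopic masses, and isotopologue envelopes."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spotscreen.chem import (
    ISOTOPES,
    PROTON_MASS,
    AdductSpec,
    ElementComposition,
    envelope_fraction_in_window,
    interference_fraction,
    isotope_envelope,
    monoisotopic_mz,
    parse_formula,
)

H_PLUS = AdductSpec.protonated()
H_MINUS = AdductSpec.deprotonated()
NEUTRAL = AdductSpec.neutral()


# ---------------------------------------------------------------- oracle

def brute_force_envelope(counts: dict, adduct: AdductSpec, truncation=1e-6):
    """Exhaustive isotopologue enumeration, independent of the convolution path.

    Returns (nominal offset -> abundance, nominal offset -> mean mass) after
    the same 0.01 Da merge semantics are irrelevant: peaks are aggregated per
    nominal M+k bin.  Valid for molecules up to ~40 atoms.
    """
    ion = dict(counts)
    if adduct.polarity == 1:
        ion["H"] = ion.get("H", 0) + 1
    elif adduct.polarity == -1:
        ion["H"] = ion["H"] - 1
    acc = [(0.0, 1.0)]
    for el, n in sorted(ion.items()):
        if n == 0:
            continue
        iso = ISOTOPES[el]
        el_peaks = []
        for combo in itertools.combinations_with_replacement(range(len(iso)), n):
            ks = [combo.count(i) for i in range(len(iso))]
            coeff = math.factorial(n)
            for k in ks:
                coeff //= math.factorial(k)
            prob = coeff * math.prod(p**k for k, (_, p) in zip(ks, iso))
            mass = sum(k * m for k, (m, _) in zip(ks, iso))
            el_peaks.append((mass, prob))
        acc = [(m1 + m2, p1 * p2) for m1, p1 in acc for m2, p2 in el_peaks]
    mono = sum(n * ISOTOPES[el][0][0] for el, n in ion.items())
    from spotscreen.chem import ELECTRON_MASS
    shift = {1: -ELECTRON_MASS, -1: ELECTRON_MASS, 0: 0.0}[adduct.polarity]
    # same merge/truncate/renormalize semantics as the envelope contract,
    # applied to the exhaustively enumerated peak list
    acc.sort()
    merged: list[list[float]] = []
    for m, p in acc:
        if merged and m - merged[-1][0] <= 0.01:
            tot = merged[-1][1] + p
            merged[-1][0] = (merged[-1][0] * merged[-1][1] + m * p) / tot
            merged[-1][1] = tot
        else:
            merged.append([m, p])
    total = sum(p for _, p in merged)
    kept = [(m, p) for m, p in merged if p >= truncation * total]
    norm = sum(p for _, p in kept)
    by_offset: dict[int, float] = {}
    mass_by_offset: dict[int, float] = {}
    for m, p in kept:
        k = round(m - mono)
        by_offset[k] = by_offset.get(k, 0.0) + p / norm
        mass_by_offset[k] = mass_by_offset.get(k, 0.0) + (m + shift) * p / norm
    return by_offset, {k: mass_by_offset[k] / by_offset[k] for k in by_offset}


ORACLE_FORMULAS = [
    ({"C": 1}, NEUTRAL),
    ({"C": 2}, NEUTRAL),
    ({"H": 2, "O": 1}, H_PLUS),
    ({"C": 12, "H": 15, "N": 1, "O": 2}, H_PLUS),  # 30 atoms
    ({"C": 12, "H": 17, "N": 1, "O": 2}, H_PLUS),
    ({"C": 6, "H": 12, "F": 1, "O": 8, "P": 1}, H_MINUS),  # 28 atoms
    ({"S": 2, "Cl": 2}, NEUTRAL),
    ({"C": 3, "H": 7, "Br": 1}, NEUTRAL),
    ({"C": 10, "H": 20, "N": 2, "O": 4, "S": 1}, H_PLUS),  # 37 atoms
]


@pytest.mark.parametrize("counts,adduct", ORACLE_FORMULAS,
                         ids=[ElementComposition(c).hill_formula() for c, _ in ORACLE_FORMULAS])
def test_envelope_matches_brute_force_enumeration(counts, adduct):
    """Convolution envelope equals exhaustive isotopologue enumeration to 1e-9.

    Compared at a truncation of 1e-12 so that the check probes the
    distribution computation itself rather than which borderline peaks the
    two paths happen to drop at the default cutoff.
    """
    env = isotope_envelope(ElementComposition(counts), adduct, truncation=1e-12)
    oracle_ab, oracle_mass = brute_force_envelope(counts, adduct, truncation=1e-12)
    got_ab: dict[int, float] = {}
    got_mass: dict[int, float] = {}
    for m, a, k in zip(env.masses, env.abundances, env.nominal_offsets):
        got_ab[int(k)] = got_ab.get(int(k), 0.0) + float(a)
        got_mass[int(k)] = got_mass.get(int(k), 0.0) + m * float(a)
    for k in got_mass:
        got_mass[k] /= got_ab[k]
    all_k = set(oracle_ab) | set(got_ab)
    for k in all_k:
        assert abs(oracle_ab.get(k, 0.0) - got_ab.get(k, 0.0)) <= 1e-9, f"M+{k}"
    for k in set(oracle_mass) & set(got_mass):
        if oracle_ab[k] >= 1e-6:  # mean mass of dust-level tails is ill-conditioned
            assert oracle_mass[k] == pytest.approx(got_mass[k], abs=1e-6)


# ---------------------------------------------------------------- parsing

@pytest.mark.parametrize("text,expected", [
    ("C12H15NO2", {"C": 12, "H": 15, "N": 1, "O": 2}),
    ("H2O", {"H": 2, "O": 1}),
    ("C6H12FO8P", {"C": 6, "H": 12, "F": 1, "O": 8, "P": 1}),
    ("ClH", {"Cl": 1, "H": 1}),  # non-Hill input order accepted
])
def test_parse_formula(text, expected):
    comp = parse_formula(text)
    assert comp.counts == expected
    assert parse_formula(comp.hill_formula()).counts == expected  # round trip


def test_parse_formula_rejects_unknown_element_and_empty():
    with pytest.raises(ValueError, match="Xx"):
        parse_formula("Xx2O")
    with pytest.raises(ValueError):
        parse_formula("")
    with pytest.raises(ValueError):
        parse_formula("C12h15")  # lowercase start of token is malformed


def test_hill_order_without_carbon_is_alphabetical():
    assert parse_formula("OH2").hill_formula() == "H2O"
    assert parse_formula("C2H6O").hill_formula() == "C2H6O"


# ---------------------------------------------------------------- masses

@pytest.mark.parametrize("formula,adduct,expected,decimals", [
    ("C12H15NO2", H_PLUS, 206.118, 3),
    ("C12H17NO2", H_PLUS, 208.133, 3),
    ("H2O", H_PLUS, 19.018, 3),
])
def test_monoisotopic_mz(formula, adduct, expected, decimals):
    assert monoisotopic_mz(parse_formula(formula), adduct) == pytest.approx(
        expected, abs=0.5 * 10**-decimals)


def test_neutral_adduct_has_no_mz_shift_and_ionic_needs_charge():
    comp = parse_formula("C12H15NO2")
    m_neutral = monoisotopic_mz(comp, NEUTRAL)
    assert monoisotopic_mz(comp, H_PLUS) == pytest.approx(m_neutral + PROTON_MASS, abs=1e-9)


def test_two_hydrogen_shift_close_to_two_mass_units():
    """An imine-to-amine reduction adds 2 H: product sits ~2 Da above substrate."""
    d = (monoisotopic_mz(parse_formula("C12H17NO2"), H_PLUS)
         - monoisotopic_mz(parse_formula("C12H15NO2"), H_PLUS))
    assert d == pytest.approx(2.016, abs=0.001)
    assert abs(d - 2.0) < 0.2  # inside one channel window of the nominal +2


@given(st.dictionaries(st.sampled_from(sorted(ISOTOPES)), st.integers(1, 8),
                       min_size=1, max_size=4))
def test_proton_rule_for_all_compositions(counts):
    """mz([M+H]+) - mz([M-H]-) = 2 x proton mass for every composition."""
    counts = dict(counts)
    counts["H"] = counts.get("H", 0) + 2  # ensure deprotonation possible
    comp = ElementComposition(counts)
    assert (monoisotopic_mz(comp, H_PLUS) - monoisotopic_mz(comp, H_MINUS)
            ) == pytest.approx(2 * PROTON_MASS, abs=1e-12)


# ---------------------------------------------------------------- envelopes

def test_single_carbon_envelope_is_the_abundance_table():
    env = isotope_envelope(ElementComposition({"C": 1}), NEUTRAL)
    assert env.masses == pytest.approx([12.0, 13.0033548351], abs=1e-9)
    assert env.abundances == pytest.approx([0.9893, 0.0107], abs=1e-12)


def test_two_carbon_m1_is_binomial():
    env = isotope_envelope(ElementComposition({"C": 2}), NEUTRAL)
    m1 = float(env.abundances[env.nominal_offsets == 1].sum())
    assert m1 == pytest.approx(2 * 0.9893 * 0.0107, rel=1e-9)


def test_substrate_m2_coincides_with_product_channel(imine_amine):
    """The substrate's M+2 isotopologue falls within 0.2 Da of the product ion."""
    sub, prod, H = imine_amine
    env = isotope_envelope(sub, H)
    m2_mass = float(env.masses[env.nominal_offsets == 2][0])
    assert abs(m2_mass - monoisotopic_mz(prod, H)) < 0.2


@given(st.dictionaries(st.sampled_from(sorted(ISOTOPES)), st.integers(1, 10),
                       min_size=1, max_size=3))
def test_envelope_is_probability_distribution(counts):
    env = isotope_envelope(ElementComposition(counts), NEUTRAL)
    assert float(env.abundances.sum()) == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(env.masses) > 0)
    assert np.all(env.abundances > 0)


def test_truncation_bounds_are_enforced():
    comp = ElementComposition({"C": 5})
    with pytest.raises(ValueError):
        isotope_envelope(comp, NEUTRAL, truncation=0.0)
    with pytest.raises(ValueError):
        isotope_envelope(comp, NEUTRAL, truncation=0.5)


# ---------------------------------------------------------------- interference

def test_interference_fraction_of_m2_into_product_channel(imine_amine):
    sub, prod, H = imine_amine
    env = isotope_envelope(sub, H)
    frac = interference_fraction(env, monoisotopic_mz(prod, H), 0.2)
    # equals M+2 / M+0 because the base peak is monoisotopic
    m2 = float(env.abundances[env.nominal_offsets == 2].sum())
    m0 = float(env.abundances[env.nominal_offsets == 0].sum())
    assert frac == pytest.approx(m2 / m0, rel=1e-12)
    assert frac == pytest.approx(0.012, abs=0.002)


def test_interference_at_base_peak_is_at_least_one(imine_amine):
    sub, _, H = imine_amine
    env = isotope_envelope(sub, H)
    base_mass = float(env.masses[np.argmax(env.abundances)])
    assert interference_fraction(env, base_mass, 0.2) >= 1.0


def test_interference_zero_far_from_envelope(imine_amine):
    sub, _, H = imine_amine
    env = isotope_envelope(sub, H)
    assert interference_fraction(env, 300.0, 0.2) == 0.0


def test_envelope_fraction_in_window_is_monoisotopic_share(imine_amine):
    sub, _, H = imine_amine
    env = isotope_envelope(sub, H)
    frac = envelope_fraction_in_window(env, monoisotopic_mz(sub, H), 0.2)
    assert frac == pytest.approx(float(env.abundances[env.nominal_offsets == 0].sum()),
                                 rel=1e-12)
    assert 0.8 < frac < 1.0
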