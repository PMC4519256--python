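import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halonet.formula import IonSpecies, MolecularFormula, parse_formula
from halonet.isotopes import (
    HEAVY_SPACING,
    HalogenClass,
    IsotopePattern,
    classify_halogenation,
    find_isotopologue_ladders,
    halogen_class_of_formula,
    simulate_envelope,
)

HECTO_ION = "C27H35O9Cl2N2S2"  # methyl-analog ion minus CH2


class TestEnvelope:
    def test_single_carbon(self):
        pat = simulate_envelope(MolecularFormula({"C": 1}), prune_below=0.0)
        # one 12C and one 13C isotopologue (as +1 ions)
        assert len(pat.entries) == 2
        ratios = {round(mz): ab for mz, ab in pat.entries}
        assert ratios[12] == pytest.approx(0.9893, abs=1e-6)
        assert ratios[13] == pytest.approx(0.0107, abs=1e-6)

    def test_cl2_binomial_oracle(self):
        """Cl2 abundances equal the direct (p+q)^2 expansion."""
        p, q = 0.7576, 0.2424
        pat = simulate_envelope(MolecularFormula({"Cl": 2}), prune_below=0.0)
        abundances = [ab for _, ab in pat.entries]
        assert abundances == pytest.approx([p * p, 2 * p * q, q * q], abs=1e-9)

    def test_hecto_ladder_nominal_masses(self):
        pat = simulate_envelope(parse_formula(HECTO_ION))
        ladder = pat.halogen_ladder().top(3)
        assert ladder.nominal_mzs() == [665, 667, 669]

    def test_ladder_spacing_is_two_daltons(self):
        pat = simulate_envelope(parse_formula(HECTO_ION)).halogen_ladder().top(3)
        mzs = [mz for mz, _ in pat.entries]
        for lo, hi in zip(mzs, mzs[1:]):
            assert hi - lo == pytest.approx(HEAVY_SPACING, abs=0.01)

    def test_mass_balance_unpruned(self):
        total = sum(ab for _, ab in simulate_envelope(parse_formula(HECTO_ION), 0.0).entries)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_pruning_only_removes_small_entries(self):
        full = simulate_envelope(parse_formula(HECTO_ION), 0.0)
        pruned = simulate_envelope(parse_formula(HECTO_ION), 1e-4)
        kept = {mz for mz, _ in pruned.entries}
        for mz, ab in full.entries:
            assert (mz in kept) == (ab >= 1e-4)

    def test_halogen_free_a2_is_background(self):
        """CHNO-only ions have only skeletal A+2 (13C2 + 18O, ~5% at
        27 carbons) and classify as halogen-free."""
        pat = simulate_envelope(parse_formula("C27H39N2O4"))
        a, a2, _ = pat.triple()
        assert a2 / a < 0.06
        assert classify_halogenation(pat).cls is HalogenClass.NONE


class TestClassifier:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((1.0, 0.97, 0.0), HalogenClass.BR1),
            ((1.0, 0.0, 0.0), HalogenClass.NONE),
            ((1.0, 0.64, 0.10), HalogenClass.CL2),
            ((1.0, 0.32, 0.0), HalogenClass.CL1),
            ((1.0, 1.29, 0.31), HalogenClass.BR1CL1),
        ],
    )
    def test_template_triples(self, triple, expected):
        entries = tuple(
            (500.0 + k * HEAVY_SPACING, ab) for k, ab in enumerate(triple) if ab > 0
        )
        assert classify_halogenation(IsotopePattern(entries)).cls is expected

    def test_single_entry_is_none(self):
        call = classify_halogenation(IsotopePattern(((500.0, 1.0),)))
        assert call.cls is HalogenClass.NONE

    @settings(max_examples=60, deadline=None)
    @given(
        cls=st.sampled_from(
            [HalogenClass.NONE, HalogenClass.CL1, HalogenClass.CL2,
             HalogenClass.BR1, HalogenClass.BR1CL1, HalogenClass.I1]
        ),
        n_c=st.integers(10, 35),
        n_o=st.integers(0, 10),
        n_s=st.integers(0, 2),
    )
    def test_round_trip_recovery(self, cls, n_c, n_o, n_s):
        """classify(simulate(f)) recovers the halogen class of random
        formulas, up to the iodine/halogen-free equivalence (iodine is
        monoisotopic and invisible to the envelope)."""
        counts = {"C": n_c, "H": int(n_c * 1.5), "N": 2, "O": n_o, "S": n_s}
        for el, n in {
            HalogenClass.NONE: {}, HalogenClass.CL1: {"Cl": 1},
            HalogenClass.CL2: {"Cl": 2}, HalogenClass.BR1: {"Br": 1},
            HalogenClass.BR1CL1: {"Cl": 1, "Br": 1}, HalogenClass.I1: {"I": 1},
        }[cls].items():
            counts[el] = n
        f = MolecularFormula(counts)
        call = classify_halogenation(simulate_envelope(IonSpecies(f, 1)))
        expected = cls if cls is not HalogenClass.I1 else HalogenClass.NONE
        assert call.cls is expected
        assert call.score > 0.9

    def test_formula_class_lookup(self):
        assert halogen_class_of_formula(parse_formula("C27H38BrN2O4")) is HalogenClass.BR1
        assert halogen_class_of_formula(parse_formula(HECTO_ION)) is HalogenClass.CL2
        assert halogen_class_of_formula(parse_formula("C27H37O4ClIN2")) is HalogenClass.CL1


class TestLadderFinding:
    def test_hecto_triple_is_one_ladder(self):
        ladders = find_isotopologue_ladders(
            [(665.11, 10.0), (667.11, 6.0), (669.10, 1.0)], spacing_tol=0.02
        )
        assert ladders == [[0, 1, 2]]

    def test_singleton(self):
        assert find_isotopologue_ladders([(455.29, 1.0)]) == [[0]]

    def test_spacing_outside_tolerance_splits(self):
        ladders = find_isotopologue_ladders([(100.0, 1.0), (103.5, 1.0)], 0.02)
        assert ladders == [[0], [1]]

    def test_a4_gap_bridged(self):
        """A and A+4 chain even when A+2 was not sampled."""
        ladders = find_isotopologue_ladders(
            [(665.11, 1.0), (665.11 + 2 * HEAVY_SPACING, 0.2)], 0.02
        )
        assert ladders == [[0, 1]]

    @settings(max_examples=50, deadline=None)
    @given(
        bases=st.lists(st.floats(150, 800), min_size=1, max_size=5, unique=True),
        sizes=st.lists(st.integers(1, 3), min_size=5, max_size=5),
    )
    def test_detected_spacing_invariant(self, bases, sizes):
        """Within any detected ladder, consecutive gaps sit at multiples
        of the heavy-isotope spacing."""
        precursors = []
        for b, n in zip(sorted(bases), sizes):
            for k in range(n):
                precursors.append((b + k * HEAVY_SPACING, 1.0))
        ladders = find_isotopologue_ladders(precursors, spacing_tol=0.02)
        assert sorted(i for lad in ladders for i in lad) == list(range(len(precursors)))
        for lad in ladders:
            mzs = [precursors[i][0] for i in lad]
            for lo, hi in zip(mzs, mzs[1:]):
                steps = (hi - lo) / HEAVY_SPACING
                assert math.isclose(steps, round(steps), abs_tol=0.02)
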