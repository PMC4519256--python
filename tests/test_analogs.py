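import pytest

from halonet.analogs import (
    BUILTIN_TRANSFORMATIONS,
    AnalogHypothesis,
    KnownCompound,
    Transformation,
    consistency_check,
    enumerate_hypotheses,
    match_hypotheses,
    verify_formula,
)
from halonet.formula import apply_transformation, parse_formula
from halonet.isotopes import HalogenClass
from halonet.network import Node

HECTO = KnownCompound("hectochlorin", parse_formula("C27H35O9Cl2N2S2"), rt=23.8)
JAM_A = KnownCompound(
    "jamaicamide A",
    apply_transformation(parse_formula("C27H38BrN2O4"), "+Cl-H"),
    rt=None,
)


def _by_chain(hyps, *names):
    want = tuple(sorted(names))
    for h in hyps:
        if tuple(sorted(h.chain)) == want:
            return h
    raise AssertionError(f"no hypothesis with chain {names}")


class TestEnumeration:
    def test_deacyl_dechloro_methyl_masses(self):
        hyps = enumerate_hypotheses(HECTO, BUILTIN_TRANSFORMATIONS, max_steps=1)
        assert _by_chain(hyps, "deacylation").mz == pytest.approx(623.1050, abs=2e-4)
        assert _by_chain(hyps, "dechlorination").mz == pytest.approx(631.1545, abs=2e-4)
        assert _by_chain(hyps, "methylation").mz == pytest.approx(679.1312, abs=2e-4)

    def test_analog_nominal_mass_family(self):
        """The one-step analog set reproduces the deduced-analog nominal
        masses 623, 631 and 679 around the 665 parent."""
        hyps = enumerate_hypotheses(HECTO, BUILTIN_TRANSFORMATIONS, max_steps=1)
        nominals = {round(h.mz) for h in hyps}
        assert {623, 631, 679} <= nominals

    def test_bromine_to_iodine_swap(self):
        hyps = enumerate_hypotheses(JAM_A, BUILTIN_TRANSFORMATIONS, max_steps=1)
        assert _by_chain(hyps, "Br->I").mz == pytest.approx(615.1481, abs=2e-4)

    def test_two_step_chain_reaches_nonhalogenated_analog(self):
        """Dechlorination + debromination of the parent predicts the
        fully dehalogenated species at 455.2904."""
        hyps = enumerate_hypotheses(JAM_A, BUILTIN_TRANSFORMATIONS, max_steps=2)
        h = _by_chain(hyps, "dechlorination", "debromination")
        assert h.mz == pytest.approx(455.2904, abs=2e-4)

    def test_infeasible_chains_skipped(self):
        no_halogen = KnownCompound("x", parse_formula("C10H20O2"))
        hyps = enumerate_hypotheses(no_halogen, BUILTIN_TRANSFORMATIONS, max_steps=1)
        chains = {h.chain for h in hyps}
        assert ("dechlorination",) not in chains
        assert ("Br->I",) not in chains

    def test_net_zero_chains_excluded(self):
        hyps = enumerate_hypotheses(HECTO, BUILTIN_TRANSFORMATIONS, max_steps=2)
        assert all(h.formula != HECTO.ion_formula for h in hyps)

    def test_sorted_and_unique(self):
        hyps = enumerate_hypotheses(HECTO, BUILTIN_TRANSFORMATIONS, max_steps=2)
        mzs = [h.mz for h in hyps]
        assert mzs == sorted(mzs)
        assert len({h.formula for h in hyps}) == len(hyps)


class TestMatching:
    def test_printed_observed_masses_match_with_printed_errors(self):
        jam_d = AnalogHypothesis(
            "jamaicamide A", ("dechlorination",),
            parse_formula("C27H38BrN2O4"), 533.2009,
        )
        jam_e = AnalogHypothesis(
            "jamaicamide A", ("dechlorination", "debromination"),
            parse_formula("C27H39N2O4"), 455.2904,
        )
        nodes = [
            Node("n533", 533.1983, rt=29.9),
            Node("n455", 455.2877, rt=26.5),
            Node("n665", 665.1156, rt=23.8),
        ]
        out = match_hypotheses([jam_d, jam_e], nodes, tol_mamu=5.0)
        assert out[0].node_id == "n533"
        assert out[0].error_mamu == pytest.approx(-2.6, abs=0.05)
        assert out[1].node_id == "n455"
        assert out[1].error_mamu == pytest.approx(-2.7, abs=0.05)

    def test_unmatched_when_out_of_tolerance(self):
        h = AnalogHypothesis("p", ("methylation",), parse_formula("C10H22"), 143.1794)
        out = match_hypotheses([h], [Node("n", 150.0)], tol_mamu=5.0)
        assert not out[0].matched

    def test_shared_node_flagged_ambiguous(self):
        a = AnalogHypothesis("p", ("a",), parse_formula("C10H22"), 143.1794)
        b = AnalogHypothesis("p", ("b",), parse_formula("C9H18O"), 143.1430)
        out = match_hypotheses([a, b], [Node("n", 143.1600)], tol_mamu=50.0)
        assert all(h.node_id == "n" for h in out)
        assert all(h.ambiguous for h in out)


class TestVerifyFormula:
    def test_amide_vs_acid_candidates(self):
        """The observed peptide mass picks the amide composition over
        the protonated free-acid alternative."""
        amide = parse_formula("C22H36N3O5")
        acid_h = parse_formula("C22H35N2O6")  # [M+H]+ of C22H34N2O6
        best, err = verify_formula(422.2648, [amide, acid_h], tol_mamu=5.0)
        assert best == amide
        assert err == pytest.approx(-0.1, abs=0.05)

    def test_exact_match_zero_error(self):
        f = parse_formula("C27H39N2O4")
        best, err = verify_formula(455.2904, [f])
        assert best == f and abs(err) <= 0.05

    def test_all_too_far_returns_none(self):
        best, err = verify_formula(400.0, [parse_formula("C27H39N2O4")], tol_mamu=5.0)
        assert best is None and err is None


class TestConsistency:
    def _matched(self, formula, chain=("dechlorination",)):
        f = parse_formula(formula)
        return AnalogHypothesis(
            "hectochlorin", chain, f, 0.0, node_id="n", node_mz=0.0, error_mamu=0.0
        )

    def test_bromine_only_analog_consistent_with_br1_envelope(self):
        h = consistency_check(
            self._matched("C27H38BrN2O4"), HalogenClass.BR1, rt=29.9, parent_rt=23.8
        )
        assert h.halogen_consistent is True
        assert h.source_fragment_warning is False

    def test_dichloro_formula_vs_halogen_free_envelope(self):
        h = consistency_check(
            self._matched("C27H35O9Cl2N2S2"), HalogenClass.NONE, rt=20.0, parent_rt=23.8
        )
        assert h.halogen_consistent is False

    def test_coeluting_match_warned_as_source_fragment(self):
        h = consistency_check(
            self._matched("C27H38BrN2O4"), HalogenClass.BR1, rt=23.9, parent_rt=23.8
        )
        assert h.source_fragment_warning is True

    def test_iodinated_formula_matches_envelope_silent_class(self):
        h = consistency_check(
            self._matched("C27H39IN2O4"), HalogenClass.NONE, rt=29.4, parent_rt=23.8
        )
        assert h.halogen_consistent is True


def test_custom_transformation_from_delta_string():
    t = Transformation("hydroxylation", "+O")
    assert t.delta == {"O": 1}
    with pytest.raises(ValueError):
        Transformation("null", {"C": 0})
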