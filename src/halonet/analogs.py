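"""Analog hypothesis generation and exact-mass dereplication.

Starting from a known compound's [M+H]+ composition, small structural
transformations — deacylation, (de)halogenation, (de)methylation,
halogen swaps — are applied singly or in pairs to propose analog ion
formulas.  Each hypothesis predicts an exact m/z; cluster nodes within
a few mamu of a prediction are candidate analogs.  Two plausibility
flags are recorded (never auto-rejected): the isotope-envelope halogen
class of the node must match the predicted composition, and the
retention time must differ from the parent's (a co-eluting match is
likely an in-source fragment, not a new compound).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .formula import (
    FormulaError,
    IonSpecies,
    MolecularFormula,
    apply_transformation,
    mass_error_mamu,
    mz_of_ion,
    parse_delta,
)
from .isotopes import HalogenClass, halogen_class_of_formula
from .network import Node

__all__ = [
    "KnownCompound",
    "Transformation",
    "BUILTIN_TRANSFORMATIONS",
    "AnalogHypothesis",
    "enumerate_hypotheses",
    "match_hypotheses",
    "verify_formula",
    "consistency_check",
    "TOL_MAMU",
]

#: Default hypothesis-matching tolerance, mamu (~5 ppm at m/z 600).
TOL_MAMU: float = 5.0

#: Default retention-time window (min) inside which a match is flagged
#: as a possible in-source fragment of the parent.
RT_TOL_MIN: float = 0.5


@dataclass(frozen=True)
class KnownCompound:
    """A dereplication seed: name, [M+H]+ composition, optional RT."""

    name: str
    ion_formula: MolecularFormula
    rt: float | None = None

    @property
    def mz(self) -> float:
        return mz_of_ion(IonSpecies(self.ion_formula, 1))


@dataclass(frozen=True)
class Transformation:
    """A named signed element-count delta, e.g. dechlorination = −Cl+H."""

    name: str
    delta: Mapping[str, int]

    def __post_init__(self) -> None:
        if isinstance(self.delta, str):
            object.__setattr__(self, "delta", parse_delta(self.delta))
        clean = {el: n for el, n in self.delta.items() if n != 0}
        if not clean:
            raise ValueError(f"transformation {self.name!r} has empty delta")
        object.__setattr__(self, "delta", clean)


BUILTIN_TRANSFORMATIONS: tuple[Transformation, ...] = (
    Transformation("deacylation", {"C": -2, "H": -2, "O": -1}),
    Transformation("dechlorination", {"Cl": -1, "H": 1}),
    Transformation("debromination", {"Br": -1, "H": 1}),
    Transformation("methylation", {"C": 1, "H": 2}),
    Transformation("demethylation", {"C": -1, "H": -2}),
    Transformation("Br->I", {"Br": -1, "I": 1}),
    Transformation("chlorination", {"Cl": 1, "H": -1}),
    Transformation("bromination", {"Br": 1, "H": -1}),
)


@dataclass(frozen=True)
class AnalogHypothesis:
    """One predicted analog of a known parent compound."""

    parent: str
    chain: tuple[str, ...]
    formula: MolecularFormula
    mz: float
    node_id: str | None = None
    node_mz: float | None = None
    error_mamu: float | None = None
    halogen_consistent: bool | None = None
    source_fragment_warning: bool | None = None
    ambiguous: bool = False

    @property
    def matched(self) -> bool:
        return self.node_id is not None


def enumerate_hypotheses(
    k: KnownCompound,
    transformations: Sequence[Transformation] = BUILTIN_TRANSFORMATIONS,
    max_steps: int = 2,
) -> list[AnalogHypothesis]:
    """All analog formulas reachable in <= ``max_steps`` transformations.

    Chains are order-insensitive multisets; infeasible chains (negative
    element counts) and chains whose net delta is zero (they predict the
    parent itself) are skipped; duplicate predicted formulas collapse to
    the shortest chain.  Output is ordered by predicted m/z.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    seen: dict[MolecularFormula, AnalogHypothesis] = {}
    for n_steps in range(1, max_steps + 1):
        for combo in itertools.combinations_with_replacement(
            transformations, n_steps
        ):
            f = k.ion_formula
            try:
                for t in combo:
                    f = apply_transformation(f, t.delta)
            except FormulaError:
                continue
            if f == k.ion_formula:
                continue  # net-zero chain predicts the parent
            if f in seen:
                continue  # shortest chain wins (outer loop is by length)
            chain = tuple(t.name for t in combo)
            seen[f] = AnalogHypothesis(
                parent=k.name,
                chain=chain,
                formula=f,
                mz=mz_of_ion(IonSpecies(f, 1)),
            )
    return sorted(seen.values(), key=lambda h: (h.mz, h.chain))


def match_hypotheses(
    hypotheses: Sequence[AnalogHypothesis],
    cluster: Sequence[Node],
    tol_mamu: float = TOL_MAMU,
) -> list[AnalogHypothesis]:
    """Match predicted analog masses against cluster nodes.

    Each hypothesis is assigned the node minimizing |observed −
    predicted| and kept as matched iff that error is within
    ``tol_mamu``.  A node may support several hypotheses; such
    ambiguity is preserved and flagged rather than resolved (resolving
    it needs orthogonal evidence such as NMR).
    """
    if not cluster:
        raise ValueError("empty cluster")
    out: list[AnalogHypothesis] = []
    node_usage: dict[str, int] = {}
    for h in hypotheses:
        best_node = None
        best_err = None
        for n in cluster:
            err = mass_error_mamu(n.precursor_mz, h.mz)
            if best_err is None or abs(err) < abs(best_err):
                best_node, best_err = n, err
        if best_node is not None and best_err is not None and abs(best_err) <= tol_mamu:
            out.append(
                replace(
                    h,
                    node_id=best_node.id,
                    node_mz=best_node.precursor_mz,
                    error_mamu=best_err,
                )
            )
            node_usage[best_node.id] = node_usage.get(best_node.id, 0) + 1
        else:
            out.append(h)
    return [
        replace(h, ambiguous=bool(h.node_id and node_usage.get(h.node_id, 0) > 1))
        for h in out
    ]


def verify_formula(
    observed_mz: float,
    candidates: Sequence[MolecularFormula],
    tol_mamu: float = TOL_MAMU,
) -> tuple[MolecularFormula | None, float | None]:
    """Pick the candidate [M+H]+ composition best explaining a mass.

    Returns (formula, signed error in mamu), or (None, None) when every
    candidate is farther than ``tol_mamu`` from the observation.
    """
    if not candidates:
        raise ValueError("no candidate formulas")
    best: MolecularFormula | None = None
    best_err: float | None = None
    for f in candidates:
        err = mass_error_mamu(observed_mz, mz_of_ion(IonSpecies(f, 1)))
        if best_err is None or abs(err) < abs(best_err):
            best, best_err = f, err
    if best_err is not None and abs(best_err) <= tol_mamu:
        return best, best_err
    return None, None


def consistency_check(
    h: AnalogHypothesis,
    node_halogen_class: HalogenClass | None,
    rt: float | None,
    parent_rt: float | None,
    rt_tol: float = RT_TOL_MIN,
) -> AnalogHypothesis:
    """Record plausibility flags on a matched hypothesis.

    ``halogen_consistent``: the predicted composition's halogen class
    equals the observed node class (iodine counts as envelope-silent).
    ``source_fragment_warning``: the node co-elutes with the parent
    within ``rt_tol`` minutes, so it may be an in-source fragment.
    Neither flag rejects the hypothesis.
    """
    predicted = halogen_class_of_formula(h.formula)
    consistent: bool | None = None
    if node_halogen_class is not None:
        obs = node_halogen_class
        # The classifier cannot see iodine; fold I1 into NONE on both sides.
        fold = {HalogenClass.I1: HalogenClass.NONE}
        consistent = fold.get(predicted, predicted) == fold.get(obs, obs)
    warn: bool | None = None
    if rt is not None and parent_rt is not None:
        warn = abs(rt - parent_rt) <= rt_tol
    return replace(h, halogen_consistent=consistent, source_fragment_warning=warn)


def hypotheses_table_rows(hypotheses: Sequence[AnalogHypothesis]) -> list[dict]:
    """Flat dict rows for the analog report TSV."""
    rows = []
    for h in hypotheses:
        rows.append(
            {
                "parent": h.parent,
                "chain": "+".join(h.chain),
                "predicted_formula": h.formula.format(),
                "predicted_mz": round(h.mz, 4),
                "node_id": h.node_id or "",
                "node_mz": "" if h.node_mz is None else round(h.node_mz, 4),
                "error_mamu": "" if h.error_mamu is None else h.error_mamu,
                "halogen_consistent": _flag(h.halogen_consistent),
                "rt_flag": _flag(h.source_fragment_warning),
                "ambiguous": _flag(h.ambiguous),
            }
        )
    return rows


def _flag(v: bool | None) -> str:
    return "" if v is None else ("yes" if v else "no")
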