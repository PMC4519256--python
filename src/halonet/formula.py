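"""Molecular formulas and exact monoisotopic mass arithmetic.

The unit of all mass bookkeeping in this package is the elemental
composition of an *ion* — for protonated natural products the ``[M+H]+``
composition with the extra proton already counted.  Masses are computed
from an embedded IUPAC monoisotopic table and the electron mass is
subtracted per unit of positive charge, which is what high-resolution
instruments report and what "calculated" values in dereplication tables
mean.

Mass errors are expressed in mamu (milli-atomic-mass-units, i.e. mDa),
signed as observed minus calculated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "FormulaError",
    "MolecularFormula",
    "IonSpecies",
    "parse_formula",
    "parse_delta",
    "mz_of_ion",
    "mass_error_mamu",
    "apply_transformation",
]

#: Monoisotopic atomic masses (Da), most abundant isotope per element.
#: IUPAC values; carbon-12 is exact by definition.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.00307400443,
    "O": 15.99491461957,
    "P": 30.97376199842,
    "S": 31.9720711744,
    "F": 18.99840316273,
    "Cl": 34.968852682,
    "Br": 78.9183376,
    "I": 126.9044719,
}

#: Electron rest mass in Da.
ELECTRON_MASS: float = 0.000548579909


class FormulaError(ValueError):
    """Raised for unparsable formula strings or infeasible compositions."""


# One element token: capital letter plus optional lowercase, optional count.
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_SIGNED_TOKEN = re.compile(r"([+-]?)((?:[A-Z][a-z]?\d*)+)")


@dataclass(frozen=True, eq=False)
class MolecularFormula:
    """Elemental composition of a neutral or ion species.

    Counts are non-negative; unknown element symbols are rejected at
    construction.  Equality is element-wise; zero counts are dropped so
    ``CH4O0 == CH4``.  Hashable, so formulas can key dicts and sets.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return self.counts == other.counts

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"negative or non-integer count for {el}: {n}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    @property
    def monoisotopic_mass(self) -> float:
        """Sum of monoisotopic atomic masses, Da (no electron correction)."""
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts.items())

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def halogen_counts(self) -> dict[str, int]:
        """Counts of Cl, Br, I present (F excluded: monoisotopic anyway)."""
        return {el: self[el] for el in ("Cl", "Br", "I") if self[el]}

    def format(self) -> str:
        """Canonical Hill-order string: C, H, then remaining alphabetically."""
        parts = []
        for el in ("C", "H"):
            if self[el]:
                parts.append(el + (str(self[el]) if self[el] != 1 else ""))
        for el in sorted(set(self.counts) - {"C", "H"}):
            parts.append(el + (str(self[el]) if self[el] != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


@dataclass(frozen=True)
class IonSpecies:
    """An ion: composition (protons included) plus signed charge."""

    formula: MolecularFormula
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise FormulaError("ion charge must be non-zero")

    @property
    def mz(self) -> float:
        return mz_of_ion(self)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a formula string such as ``"C27H38BrN2O4"``.

    Element order is arbitrary, an omitted count means 1, and whitespace
    or underscore markup (``C_27_H_38_...``) is tolerated.  Repeated
    element symbols accumulate.
    """
    cleaned = re.sub(r"[\s_]+", "", text)
    if not cleaned:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def parse_delta(text: str) -> dict[str, int]:
    """Parse a signed element delta such as ``"-Cl+H"`` or ``"+CH2"``.

    Each signed group applies its sign to every element in the group;
    a leading sign is optional and defaults to ``+``.
    """
    cleaned = re.sub(r"[\s_]+", "", text)
    if not cleaned:
        raise FormulaError("empty delta string")
    delta: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _SIGNED_TOKEN.match(cleaned, pos)
        if not m:
            raise FormulaError(f"cannot parse delta {text!r} at position {pos}")
        sign = -1 if m.group(1) == "-" else 1
        for el, digits in _TOKEN.findall(m.group(2)):
            if not el:
                continue
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
            delta[el] = delta.get(el, 0) + sign * (int(digits) if digits else 1)
        pos = m.end()
    return {el: n for el, n in delta.items() if n != 0}


def mz_of_ion(ion: IonSpecies) -> float:
    """Exact m/z of an ion: (Σ atomic masses − charge · m_e) / |charge|.

    For the +1 ions of this workflow this reproduces printed
    "calculated for <ion formula>" values to 4 decimal places.
    """
    if ion.charge == 0:
        raise FormulaError("ion charge must be non-zero")
    mass = ion.formula.monoisotopic_mass - ion.charge * ELECTRON_MASS
    return mass / abs(ion.charge)


def mass_error_mamu(observed: float, calculated: float) -> float:
    """Signed mass error (observed − calculated) in mamu (mDa), to 0.1."""
    return round((observed - calculated) * 1000.0, 1)


def delta_mass(delta: Mapping[str, int]) -> float:
    """Signed monoisotopic mass of an element-count delta, Da."""
    for el in delta:
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in delta")
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in delta.items())


def apply_transformation(
    f: MolecularFormula, delta: Mapping[str, int] | str
) -> MolecularFormula:
    """Apply a signed element-count delta to a formula.

    Raises :class:`FormulaError` if any resulting count would be
    negative (infeasible transformation on that scaffold).
    """
    if isinstance(delta, str):
        delta = parse_delta(delta)
    merged = dict(f.counts)
    for el, n in delta.items():
        merged[el] = merged.get(el, 0) + n
        if merged[el] < 0:
            raise FormulaError(
                f"transformation infeasible: {el} count would be {merged[el]}"
            )
    return MolecularFormula(merged)
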