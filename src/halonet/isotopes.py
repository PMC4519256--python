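"""Isotope envelope simulation and halogenation-state diagnosis.

Chlorine and bromine each have two abundant natural isotopes two mass
units apart (35Cl/37Cl at 75.8/24.2%, 79Br/81Br at 50.7/49.3%), so
halogenated ions appear as a ladder of precursor masses spaced ~2 Da —
the A, A+2, A+4 peaks — whose intensity ratios diagnose the halogen
content.  Iodine is monoisotopic and leaves no such signature.

The envelope is computed by exact multinomial convolution over every
element's isotopes (carbon and sulfur contribute visibly at A+1/A+2 for
larger molecules), aggregated by mass and pruned below a relative
abundance floor.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .formula import ELECTRON_MASS, IonSpecies, MolecularFormula

__all__ = [
    "ISOTOPES",
    "HEAVY_SPACING",
    "HalogenClass",
    "HalogenCall",
    "IsotopePattern",
    "simulate_envelope",
    "classify_halogenation",
    "halogen_class_of_formula",
    "find_isotopologue_ladders",
]

#: Per element: list of (isotope mass Da, natural abundance fraction).
#: Abundances sum to 1 within 1e-9 for every element.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "H": [(1.00782503207, 0.999885), (2.01410177812, 0.000115)],
    "N": [(14.00307400443, 0.99636), (15.00010889888, 0.00364)],
    "O": [
        (15.99491461957, 0.99757),
        (16.99913175650, 0.00038),
        (17.99915961286, 0.00205),
    ],
    "P": [(30.97376199842, 1.0)],
    "S": [
        (31.9720711744, 0.9499),
        (32.9714589098, 0.0075),
        (33.967867004, 0.0425),
        (35.96708071, 0.0001),
    ],
    "F": [(18.99840316273, 1.0)],
    "Cl": [(34.968852682, 0.7576), (36.965902602, 0.2424)],
    "Br": [(78.9183376, 0.5069), (80.9162897, 0.4931)],
    "I": [(126.9044719, 1.0)],
}

#: 37Cl − 35Cl mass difference; the A/A+2 ladder spacing (81Br − 79Br
#: is 1.99795, indistinguishable at the tolerances used here).
HEAVY_SPACING: float = 1.99705

# Masses within this window are aggregated into one isotopologue peak;
# fine structure below it is out of scope.
_MERGE_TOL = 0.0005


class HalogenClass(str, enum.Enum):
    """Halogen content classes distinguishable from an A/A+2/A+4 triple."""

    NONE = "none"
    CL1 = "Cl1"
    CL2 = "Cl2"
    BR1 = "Br1"
    BR1CL1 = "Br1Cl1"
    I1 = "I1"
    OTHER = "other"


#: Typical A+2/A contribution of the non-halogen skeleton (13C2, 18O,
#: 34S) for mid-size natural products; without it, the halogen-free
#: template loses to Cl1 on sulfur-rich compounds (two 34S atoms alone
#: contribute ~0.09 at A+2).
A2_BACKGROUND: float = 0.08


def _template_triple(cls: HalogenClass) -> tuple[float, float, float]:
    """Theoretical A/A+2/A+4 relative abundances per halogen class,
    on top of the generic organic-skeleton background."""
    p_cl, q_cl = 0.7576, 0.2424
    p_br, q_br = 0.5069, 0.4931
    r2, r4 = {
        HalogenClass.CL1: (q_cl / p_cl, 0.0),
        HalogenClass.CL2: (2 * q_cl / p_cl, (q_cl / p_cl) ** 2),
        HalogenClass.BR1: (q_br / p_br, 0.0),
        HalogenClass.BR1CL1: (
            q_cl / p_cl + q_br / p_br,
            (q_cl / p_cl) * (q_br / p_br),
        ),
        # none and I1 share the halogen-free template.
    }.get(cls, (0.0, 0.0))
    b = A2_BACKGROUND
    return (1.0, r2 + b, r4 + b * r2 + b * b)


# Candidate classes in parsimony order (fewer halogen atoms first);
# I1 is never called from a pattern alone — iodine is monoisotopic, so
# its triple is identical to NONE and ties resolve to the fewer-halogen
# class.
_TEMPLATE_ORDER = [
    HalogenClass.NONE,
    HalogenClass.CL1,
    HalogenClass.BR1,
    HalogenClass.CL2,
    HalogenClass.BR1CL1,
]


@dataclass(frozen=True)
class HalogenCall:
    """Classifier output: best class and its cosine goodness-of-fit."""

    cls: HalogenClass
    score: float


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue peaks of one ion.

    ``entries`` are (m/z, relative abundance) pairs, m/z ascending,
    abundances summing to ≤ 1 (pruning only removes mass).  ``formula``
    records provenance when the pattern was simulated.
    """

    entries: tuple[tuple[float, float], ...]
    formula: MolecularFormula | None = None

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.entries]
        if mzs != sorted(mzs):
            raise ValueError("isotope pattern entries must be sorted by m/z")

    @property
    def base_peak_mz(self) -> float:
        return max(self.entries, key=lambda e: e[1])[0]

    def normalized(self) -> "IsotopePattern":
        """Same pattern with the base (most abundant) peak scaled to 1."""
        top = max(a for _, a in self.entries)
        return IsotopePattern(
            tuple((mz, a / top) for mz, a in self.entries), self.formula
        )

    def nominal_mzs(self) -> list[int]:
        """Nominal (nearest-integer) m/z per isotopologue, as displayed
        on network node labels."""
        return [round(mz) for mz, _ in self.entries]

    def top(self, n: int) -> "IsotopePattern":
        """The n most abundant entries, returned in m/z order."""
        best = sorted(self.entries, key=lambda e: -e[1])[:n]
        return IsotopePattern(tuple(sorted(best)), self.formula)

    def halogen_ladder(self) -> "IsotopePattern":
        """The ~2 Da isotopologue ladder: entries aggregated into bins at
        even nominal offsets (A, A+2, A+4, ...) from the monoisotopic
        peak.  Odd-offset peaks (the 13C A+1 satellites) are excluded —
        they are not part of the halogen ladder displayed on a network.
        Bin m/z is the abundance-weighted mean of its members.
        """
        base_mz = self.entries[0][0]
        bins: dict[int, list[float]] = {}
        for mz, a in self.entries:
            k = round((mz - base_mz) / HEAVY_SPACING)
            if k < 0 or abs(mz - base_mz - k * HEAVY_SPACING) > 0.3:
                continue
            acc = bins.setdefault(k, [0.0, 0.0])
            acc[0] += mz * a
            acc[1] += a
        entries = tuple(
            sorted((msum / asum, asum) for msum, asum in bins.values() if asum > 0)
        )
        return IsotopePattern(entries, self.formula)

    def triple(self) -> tuple[float, float, float]:
        """A/A+2/A+4 relative abundances, aligned to the lightest peak.

        Peaks are binned by nominal offset from the monoisotopic peak;
        odd offsets (A+1, A+3) are ignored.
        """
        base_mz = self.entries[0][0]
        bins = [0.0, 0.0, 0.0]
        for mz, a in self.entries:
            k = round((mz - base_mz) / HEAVY_SPACING)
            off = mz - base_mz - k * HEAVY_SPACING
            if 0 <= k <= 2 and abs(off) < 0.5:
                bins[k] += a
        top = bins[0] if bins[0] > 0 else 1.0
        return (bins[0] / top, bins[1] / top, bins[2] / top)


def _element_pattern(el: str, n: int) -> list[tuple[float, float]]:
    """Exact multinomial isotope distribution of n atoms of one element."""
    isos = ISOTOPES[el]
    if len(isos) == 1:
        m, _ = isos[0]
        return [(m * n, 1.0)]
    out: list[tuple[float, float]] = []

    # Enumerate occupancies (k_1..k_j) over the isotopes with the exact
    # multinomial weight; negligible branches are pruned early.
    def rec(idx: int, left: int, mass: float, coeff: float, prob: float) -> None:
        if coeff * prob < 1e-15:
            return
        if idx == len(isos) - 1:
            m, p = isos[idx]
            w = coeff * prob * (p**left)
            if w >= 1e-15:
                out.append((mass + m * left, w))
            return
        m, p = isos[idx]
        for k in range(left + 1):
            rec(idx + 1, left - k, mass + m * k, coeff * math.comb(left, k), prob * (p**k))

    rec(0, n, 0.0, 1.0, 1.0)
    return _merge(out)


def _merge(peaks: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Aggregate peaks closer than the merge tolerance (abundance-weighted)."""
    peaks = sorted(peaks)
    merged: list[list[float]] = []
    for mz, a in peaks:
        if merged and mz - merged[-1][0] <= _MERGE_TOL:
            m0, a0 = merged[-1]
            tot = a0 + a
            merged[-1][0] = (m0 * a0 + mz * a) / tot if tot > 0 else m0
            merged[-1][1] = tot
        else:
            merged.append([mz, a])
    return [(m, a) for m, a in merged]


def _convolve(
    a: list[tuple[float, float]], b: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    out = [(ma + mb, pa * pb) for ma, pa in a for mb, pb in b if pa * pb >= 1e-15]
    return _merge(out)


def simulate_envelope(
    ion: IonSpecies | MolecularFormula,
    prune_below: float = 1e-4,
) -> IsotopePattern:
    """Isotope envelope of an ion by full-element multinomial convolution.

    Parameters
    ----------
    ion:
        Ion species (charge used for the electron correction and m/z
        scaling) or a bare formula, taken as charge +1.
    prune_below:
        Entries with absolute abundance below this fraction are dropped
        after the full convolution; the retained abundances are *not*
        renormalized, so they still sum to ≤ 1.
    """
    if isinstance(ion, MolecularFormula):
        ion = IonSpecies(ion, 1)
    if not (0 <= prune_below < 1):
        raise ValueError("prune_below must be in [0, 1)")
    dist: list[tuple[float, float]] = [(0.0, 1.0)]
    for el, n in sorted(ion.formula.counts.items()):
        dist = _convolve(dist, _element_pattern(el, n))
    z = ion.charge
    entries = tuple(
        sorted(
            ((m - z * ELECTRON_MASS) / abs(z), a)
            for m, a in dist
            if a >= prune_below
        )
    )
    return IsotopePattern(entries, ion.formula)


def classify_halogenation(observed: IsotopePattern) -> HalogenCall:
    """Diagnose halogen content from an observed isotopologue pattern.

    The observed A/A+2/A+4 triple is compared by cosine similarity with
    the theoretical halogen-only templates (Cl1, Cl2, Br1, Br1Cl1, and
    the halogen-free template).  Ties break toward fewer halogen atoms,
    so a pattern with no A+2 companion is called ``none`` — which also
    covers iodinated species, since iodine is monoisotopic.
    """
    if len(observed.entries) == 0:
        raise ValueError("empty isotope pattern")
    obs = observed.triple()
    if obs[1] == 0.0 and obs[2] == 0.0:
        return HalogenCall(HalogenClass.NONE, 1.0)
    best = HalogenClass.NONE
    best_score = -1.0
    for cls in _TEMPLATE_ORDER:
        tpl = _template_triple(cls)
        score = _cosine3(obs, tpl)
        if score > best_score + 1e-12:
            best, best_score = cls, score
    return HalogenCall(best, best_score)


def halogen_class_of_formula(f: MolecularFormula) -> HalogenClass:
    """True halogen class of a composition (for hypothesis consistency)."""
    ncl, nbr, ni = f["Cl"], f["Br"], f["I"]
    key = (ncl, nbr, ni)
    table = {
        (0, 0, 0): HalogenClass.NONE,
        (1, 0, 0): HalogenClass.CL1,
        (2, 0, 0): HalogenClass.CL2,
        (0, 1, 0): HalogenClass.BR1,
        (1, 1, 0): HalogenClass.BR1CL1,
        (0, 0, 1): HalogenClass.I1,
    }
    # Iodine plus nothing else is I1; iodine alongside Cl/Br falls back
    # to the Cl/Br-only classes since iodine leaves no envelope trace.
    if ni and (ncl, nbr) != (0, 0):
        key = (ncl, nbr, 0)
    return table.get(key, HalogenClass.OTHER)


def _cosine3(a: tuple[float, float, float], b: tuple[float, float, float]) -> float:
    dot = sum(x * y for x, y in zip(a, b))
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(x * x for x in b))
    if na == 0 or nb == 0:
        return 0.0
    return dot / (na * nb)


def find_isotopologue_ladders(
    precursors: list[tuple[float, float]],
    spacing_tol: float = 0.02,
) -> list[list[int]]:
    """Group precursor ions into ~2 Da isotopologue ladders.

    Precursors (m/z, intensity) are chained greedily in ascending m/z:
    an ion extends a ladder when it sits one heavy-isotope spacing
    (1.99705 Da), or two spacings (the A+4 position when A+2 was not
    sampled), above the ladder's current top, within ``spacing_tol``.
    Each precursor joins at most one ladder; ladders are returned as
    index lists ordered by their base m/z.
    """
    if not precursors:
        raise ValueError("empty precursor list")
    order = sorted(range(len(precursors)), key=lambda i: precursors[i][0])
    ladders: list[list[int]] = []
    for i in order:
        mz = precursors[i][0]
        placed = False
        for ladder in ladders:
            top = precursors[ladder[-1]][0]
            gap = mz - top
            for steps in (1, 2):
                if abs(gap - steps * HEAVY_SPACING) <= spacing_tol * steps:
                    ladder.append(i)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            ladders.append([i])
    ladders.sort(key=lambda lad: precursors[lad[0]][0])
    return ladders


def ladder_pattern(
    precursors: list[tuple[float, float]], ladder: list[int]
) -> IsotopePattern:
    """Observed isotope pattern of one detected ladder (intensity-scaled)."""
    entries = sorted((precursors[i][0], precursors[i][1]) for i in ladder)
    total = max((a for _, a in entries), default=1.0)
    if total <= 0:
        total = 1.0
    return IsotopePattern(tuple((mz, a / total) for mz, a in entries))
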