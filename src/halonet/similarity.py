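"""Cosine similarity between fragment spectra.

Two normalized fragment vectors are compared by pairing peaks within a
fragment tolerance and summing the products of their normalized
intensities.  In *shifted* (modified-cosine) mode, a peak in one
spectrum may also pair with a peak in the other offset by the precursor
mass difference — this is what lets isotopologues and structural
analogs score highly despite their halogen-bearing fragments moving in
lock-step with the parent mass.

Peak pairing is greedy over candidate pairs ordered by descending
intensity product (ties: smaller |Δm/z|, then lower m/z), each peak
used at most once across the direct and shifted windows combined.  The
greedy matcher agrees with the exhaustive optimal assignment on small
spectra (property-tested) and is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .spectra import MIN_PEAKS, Dataset, Spectrum, eligible, normalize

__all__ = ["PeakMatch", "SimilarityResult", "cosine", "pairwise_scores", "FRAG_TOL"]

#: Default fragment tolerance (Da), sized for low-resolution ion-trap MS2.
FRAG_TOL: float = 0.3


@dataclass(frozen=True)
class PeakMatch:
    """A matched peak pair: indices into each spectrum's peak list."""

    index_a: int
    index_b: int
    shifted: bool
    product: float


@dataclass(frozen=True)
class SimilarityResult:
    """Cosine score in [0, 1], matched-peak count and precursor delta."""

    score: float
    n_matched: int
    precursor_delta: float
    matches: tuple[PeakMatch, ...] = ()


def cosine(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float = FRAG_TOL,
    allow_shift: bool = True,
    scaling: Literal["sqrt", "raw"] = "sqrt",
    min_peaks: int = MIN_PEAKS,
) -> SimilarityResult:
    """Modified-cosine similarity of two fragment spectra.

    Parameters
    ----------
    a, b:
        Spectra; both must be eligible (>= ``min_peaks`` fragments).
    frag_tol:
        Fragment m/z tolerance in Da for pairing peaks.
    allow_shift:
        Also allow pairs offset by the precursor mass difference
        (modified cosine).  With ``False`` this is the plain cosine.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    if not eligible(a, min_peaks) or not eligible(b, min_peaks):
        raise ValueError(
            f"both spectra need >= {min_peaks} peaks for cosine scoring"
        )
    va = normalize(a, scaling)
    vb = normalize(b, scaling)
    delta = a.precursor_mz - b.precursor_mz

    # Candidate pairs under the direct window and (optionally) the
    # precursor-shifted window.
    candidates: list[tuple[float, float, int, int, bool]] = []
    for i, (mza, ia) in enumerate(va):
        for j, (mzb, ib) in enumerate(vb):
            direct = abs(mza - mzb) <= frag_tol
            shifted = allow_shift and abs(delta) > 1e-9 and abs(
                mza - (mzb + delta)
            ) <= frag_tol
            if direct or shifted:
                dmz = abs(mza - mzb) if direct else abs(mza - (mzb + delta))
                candidates.append((ia * ib, dmz, i, j, not direct and shifted))

    # Greedy: best product first; ties by smaller |Δm/z| then lower m/z.
    # The m/z key is symmetric in the two spectra so cosine(a, b) and
    # cosine(b, a) walk the same candidate order.
    candidates.sort(
        key=lambda c: (
            -c[0],
            c[1],
            min(va[c[2]][0], vb[c[3]][0]),
            max(va[c[2]][0], vb[c[3]][0]),
        )
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[PeakMatch] = []
    score = 0.0
    for product, _dmz, i, j, was_shifted in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append(PeakMatch(i, j, was_shifted, product))
        score += product
    return SimilarityResult(
        score=min(score, 1.0 + 1e-9),
        n_matched=len(matches),
        precursor_delta=delta,
        matches=tuple(matches),
    )


def pairwise_scores(
    d: Dataset,
    frag_tol: float = FRAG_TOL,
    allow_shift: bool = True,
    scaling: Literal["sqrt", "raw"] = "sqrt",
    min_peaks: int = MIN_PEAKS,
) -> list[tuple[int, int, SimilarityResult]]:
    """Score all unordered spectrum pairs of an eligible-filtered dataset.

    Returns (i, j, result) triples for i < j in deterministic order.
    """
    out: list[tuple[int, int, SimilarityResult]] = []
    spectra = d.spectra
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            out.append(
                (
                    i,
                    j,
                    cosine(
                        spectra[i],
                        spectra[j],
                        frag_tol=frag_tol,
                        allow_shift=allow_shift,
                        scaling=scaling,
                        min_peaks=min_peaks,
                    ),
                )
            )
    return out
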