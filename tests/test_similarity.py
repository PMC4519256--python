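import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halonet.simulate import SimulationConfig, simulate_dataset
from halonet.similarity import cosine, pairwise_scores
from halonet.spectra import Dataset, Peak, Spectrum, normalize

from conftest import random_spectrum


def optimal_score(a, b, frag_tol=0.3, allow_shift=True, scaling="sqrt"):
    """Independent oracle: exhaustive optimal one-to-one peak matching
    as a maximum-weight bipartite assignment."""
    from scipy.optimize import linear_sum_assignment

    va, vb = normalize(a, scaling), normalize(b, scaling)
    delta = a.precursor_mz - b.precursor_mz
    w = np.zeros((len(va), len(vb)))
    for i, (mza, ia) in enumerate(va):
        for j, (mzb, ib) in enumerate(vb):
            ok = abs(mza - mzb) <= frag_tol or (
                allow_shift and abs(delta) > 1e-9 and abs(mza - (mzb + delta)) <= frag_tol
            )
            if ok:
                w[i, j] = ia * ib
    rows, cols = linear_sum_assignment(-w)
    return float(w[rows, cols].sum())


def test_self_similarity_is_one(rng):
    s = random_spectrum(rng, "s")
    res = cosine(s, s)
    assert res.score == pytest.approx(1.0, abs=1e-9)
    assert res.n_matched == s.n_peaks


def test_disjoint_spectra_score_zero(spectrum_factory):
    a = spectrum_factory([(100.0 + 10 * i, 1.0) for i in range(6)], precursor_mz=500.0)
    b = spectrum_factory([(105.0 + 10 * i, 1.0) for i in range(6)], precursor_mz=500.0)
    res = cosine(a, b, frag_tol=0.3)
    assert res.score == 0.0
    assert res.n_matched == 0


def test_shifted_peak_recovered_by_modified_cosine(spectrum_factory):
    """A fragment offset by the precursor delta is matched only in
    shifted mode; plain cosine scores 5/6 of the maximum."""
    mzs = [100.0, 150.0, 200.0, 250.0, 300.0, 399.0]
    a = spectrum_factory([(m, 1.0) for m in mzs], precursor_mz=500.0)
    b = spectrum_factory(
        [(m, 1.0) for m in mzs[:-1]] + [(401.0, 1.0)], precursor_mz=502.0
    )
    plain = cosine(a, b, allow_shift=False)
    shifted = cosine(a, b, allow_shift=True)
    assert plain.score == pytest.approx(5 / 6, abs=1e-9)
    assert shifted.score == pytest.approx(1.0, abs=1e-9)
    assert shifted.score == pytest.approx(optimal_score(a, b), abs=1e-9)
    assert sum(1 for m in shifted.matches if m.shifted) == 1


def test_ineligible_spectrum_rejected(spectrum_factory):
    small = spectrum_factory([(100.0, 1.0)] , precursor_mz=300.0)
    big = spectrum_factory([(100.0 + i, 1.0) for i in range(6)])
    with pytest.raises(ValueError):
        cosine(small, big)


def test_greedy_equals_optimal_oracle_on_1000_pairs():
    """Greedy matching reproduces the exhaustive optimal assignment on
    random centroided spectrum pairs with <= 8 peaks."""
    rng = np.random.default_rng(987654)
    specs = [random_spectrum(rng, f"s{i}") for i in range(2000)]
    worst = 0.0
    for k in range(1000):
        a, b = specs[2 * k], specs[2 * k + 1]
        worst = max(worst, abs(cosine(a, b).score - optimal_score(a, b)))
    assert worst <= 1e-6


@settings(max_examples=150, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), shift=st.booleans())
def test_score_bounds_and_symmetry(seed, shift):
    rng = np.random.default_rng(seed)
    a = random_spectrum(rng, "a")
    b = random_spectrum(rng, "b")
    ab = cosine(a, b, allow_shift=shift)
    ba = cosine(b, a, allow_shift=shift)
    assert 0.0 <= ab.score <= 1.0 + 1e-9
    assert ab.score == pytest.approx(ba.score, abs=1e-9)
    assert ab.n_matched == ba.n_matched
    # greedy never exceeds the optimal assignment
    assert ab.score <= optimal_score(a, b, allow_shift=shift) + 1e-9


def test_losing_shared_peaks_never_helps(spectrum_factory):
    """Score decreases monotonically as shared peaks are replaced by
    unmatched ones."""
    base = [(100.0 + 50 * i, float(10 + i)) for i in range(8)]
    a = spectrum_factory(base, precursor_mz=600.0)
    scores = []
    for n_lost in range(3):
        peaks = list(base)
        for k in range(n_lost):
            mz, inten = peaks[k]
            peaks[k] = (mz + 7.0, inten)  # move out of tolerance
        b = spectrum_factory(peaks, precursor_mz=600.0)
        scores.append(cosine(a, b).score)
    assert scores[0] >= scores[1] >= scores[2]


def test_pairwise_scores_combinatorics(rng):
    specs = [random_spectrum(rng, f"p{i}") for i in range(3)]
    out = pairwise_scores(Dataset(specs))
    assert [(i, j) for i, j, _ in out] == [(0, 1), (0, 2), (1, 2)]


def test_identical_dataset_all_ones(spectrum_factory):
    peaks = [(100.0 + 30 * i, 5.0 + i) for i in range(7)]
    specs = [
        spectrum_factory(peaks, precursor_mz=400.0, sid=f"s{i}") for i in range(3)
    ]
    for _, _, res in pairwise_scores(Dataset(specs)):
        assert res.score == pytest.approx(1.0, abs=1e-9)


def test_isotopologue_family_clusters_above_threshold():
    """Noise-free isotopologue/analog spectra of one family all reach
    the 0.7 shifted-cosine floor with >= 6 matched peaks."""
    cfg = SimulationConfig(n_families=1, analogs_per_family=3, n_decoys=0, seed=11).noise_free()
    ds, _ = simulate_dataset(cfg)
    for a, b in itertools.combinations(ds.spectra, 2):
        res = cosine(a, b, allow_shift=True)
        assert res.score >= 0.7
        assert res.n_matched >= 6


def test_agrees_with_matchms_modified_cosine():
    """Independent cross-check against matchms' ModifiedCosine on noisy
    simulated spectra (raw intensity scaling, same tolerance)."""
    from matchms import Spectrum as MmsSpectrum
    from matchms.similarity import ModifiedCosine

    cfg = SimulationConfig(n_families=2, analogs_per_family=2, n_decoys=2, seed=5)
    ds, _ = simulate_dataset(cfg)
    mc = ModifiedCosine(tolerance=0.3)

    def to_mms(s: Spectrum) -> MmsSpectrum:
        order = np.argsort([p.mz for p in s.peaks])
        return MmsSpectrum(
            mz=np.array([s.peaks[i].mz for i in order]),
            intensities=np.array([s.peaks[i].intensity for i in order]),
            metadata={"precursor_mz": s.precursor_mz},
            metadata_harmonization=False,
        )

    pairs = list(itertools.combinations(ds.spectra[:8], 2))
    for a, b in pairs:
        ours = cosine(a, b, scaling="raw").score
        theirs = float(mc.pair(to_mms(a), to_mms(b))["score"])
        assert ours == pytest.approx(theirs, abs=1e-6)
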