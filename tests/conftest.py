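import numpy as np
import pytest

from halonet.spectra import Peak, Spectrum


def random_spectrum(rng: np.random.Generator, sid: str, n_peaks=None,
                    min_spacing: float = 1.0) -> Spectrum:
    """A realistic centroided random spectrum: peaks spaced apart."""
    n = int(rng.integers(6, 9)) if n_peaks is None else n_peaks
    mzs: list[float] = []
    while len(mzs) < n:
        c = float(rng.uniform(100.0, 900.0))
        if all(abs(c - m) > min_spacing for m in mzs):
            mzs.append(c)
    mzs.sort()
    return Spectrum(
        id=sid,
        precursor_mz=float(rng.uniform(300.0, 900.0)),
        peaks=tuple(Peak(m, float(rng.uniform(1.0, 100.0))) for m in mzs),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230901)


@pytest.fixture
def spectrum_factory():
    def make(mz_int_pairs, precursor_mz=500.0, sid="s", rt=None):
        return Spectrum(
            id=sid,
            precursor_mz=precursor_mz,
            rt=rt,
            peaks=tuple(Peak(m, i) for m, i in mz_int_pairs),
        )

    return make
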