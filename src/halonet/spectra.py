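"""MS2 spectrum containers, MGF input/output, and vector preparation.

Spectra travel as peak lists with precursor metadata.  Before
networking, each fragment spectrum is turned into a unit vector:
intensities are square-root scaled (damping the dominance of base
peaks, the convention of the spectral-networking lineage) and scaled to
unit Euclidean norm, so a cosine between two spectra is a plain dot
product over matched peaks.  Spectra with fewer than six peaks cannot
form a meaningful vector and are excluded from networking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from pyteomics import mgf as _mgf

__all__ = [
    "Peak",
    "Spectrum",
    "Dataset",
    "MgfError",
    "read_mgf",
    "write_mgf",
    "eligible",
    "normalize",
    "MIN_PEAKS",
]

#: Minimum fragment peaks required to construct a spectral vector.
MIN_PEAKS: int = 6

#: Fragment peaks closer than this (Da) are merged on load.
PEAK_MERGE_TOL: float = 0.01


class MgfError(ValueError):
    """Raised for malformed MGF content."""


@dataclass(frozen=True)
class Peak:
    """One fragment peak: m/z (Da) and non-negative intensity."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """One MS2 scan: precursor metadata plus a sorted fragment peak list.

    ``rt`` is in minutes; ``precursor_intensity`` is the MS1 intensity
    of the selected precursor when known (second PEPMASS field), used
    for isotopologue-ladder abundance readout.
    """

    id: str
    precursor_mz: float
    charge: int = 1
    rt: float | None = None
    peaks: tuple[Peak, ...] = field(default_factory=tuple)
    precursor_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        mzs = [p.mz for p in self.peaks]
        if mzs != sorted(mzs):
            object.__setattr__(
                self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz))
            )

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        return replace(self, peaks=tuple(sorted(peaks, key=lambda p: p.mz)))


@dataclass
class Dataset:
    """A collection of MS2 spectra with unique ids."""

    spectra: list[Spectrum]
    source: str = ""

    def __post_init__(self) -> None:
        ids = [s.id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate spectrum ids in dataset")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def filtered(self, min_peaks: int = MIN_PEAKS) -> "Dataset":
        """Spectra eligible for networking (>= min_peaks fragments)."""
        return Dataset(
            [s for s in self.spectra if eligible(s, min_peaks)], self.source
        )


def merge_close_peaks(
    peaks: Iterable[Peak], tol: float = PEAK_MERGE_TOL
) -> tuple[Peak, ...]:
    """Sum intensities of peaks closer than ``tol`` (intensity-weighted
    centroid m/z), avoiding double-matching in cosine scoring."""
    ordered = sorted(peaks, key=lambda p: p.mz)
    out: list[Peak] = []
    for p in ordered:
        if out and p.mz - out[-1].mz <= tol:
            prev = out[-1]
            tot = prev.intensity + p.intensity
            mz = (
                (prev.mz * prev.intensity + p.mz * p.intensity) / tot
                if tot > 0
                else prev.mz
            )
            out[-1] = Peak(mz, tot)
        else:
            out.append(p)
    return tuple(out)


def eligible(s: Spectrum, min_peaks: int = MIN_PEAKS) -> bool:
    """True iff the spectrum has enough peaks to form a vector."""
    return s.n_peaks >= min_peaks


def normalize(
    s: Spectrum, scaling: Literal["sqrt", "raw"] = "sqrt"
) -> tuple[tuple[float, float], ...]:
    """Unit-norm fragment vector of a spectrum.

    Returns (m/z, normalized intensity) pairs: intensities are
    square-root scaled (or left raw), then divided by the Euclidean
    norm so the squared entries sum to 1.
    """
    if s.n_peaks == 0:
        raise ValueError("cannot normalize an empty spectrum")
    vals = [p.intensity for p in s.peaks]
    if scaling == "sqrt":
        vals = [math.sqrt(v) for v in vals]
    elif scaling != "raw":
        raise ValueError(f"unknown scaling mode {scaling!r}")
    norm = math.sqrt(sum(v * v for v in vals))
    if norm == 0:
        raise ValueError("cannot normalize all-zero intensities")
    return tuple((p.mz, v / norm) for p, v in zip(s.peaks, vals))


def read_mgf(path: str | Path, merge_tol: float = PEAK_MERGE_TOL) -> Dataset:
    """Read an MGF file into a :class:`Dataset`.

    RTINSECONDS is converted to minutes; a missing CHARGE defaults to
    +1; peaks closer than ``merge_tol`` are intensity-summed.  A block
    without PEPMASS, or a non-numeric peak line, raises
    :class:`MgfError` naming the block.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    try:
        with _mgf.MGF(str(path), convert_arrays=1) as reader:
            for idx, entry in enumerate(reader):
                spectra.append(_spectrum_from_mgf(entry, idx, merge_tol))
    except MgfError:
        raise
    except Exception as exc:  # pyteomics raises on structural errors
        raise MgfError(f"malformed MGF block in {path.name}: {exc}") from exc
    return Dataset(spectra, source=str(path))


def _spectrum_from_mgf(entry: dict, idx: int, merge_tol: float) -> Spectrum:
    params = entry.get("params", {})
    pepmass = params.get("pepmass")
    if pepmass is None:
        raise MgfError(f"MGF block {idx}: missing PEPMASS")
    if isinstance(pepmass, (tuple, list)):
        prec_mz = float(pepmass[0])
        prec_int = (
            float(pepmass[1])
            if len(pepmass) > 1 and pepmass[1] is not None
            else None
        )
    else:
        prec_mz, prec_int = float(pepmass), None
    charge_field = params.get("charge")
    charge = int(charge_field[0]) if charge_field else 1
    rt = params.get("rtinseconds")
    rt_min = float(rt) / 60.0 if rt is not None else None
    title = str(params.get("title", f"scan_{idx}"))
    mzs = entry.get("m/z array")
    ints = entry.get("intensity array")
    if mzs is None or ints is None or len(mzs) != len(ints):
        raise MgfError(f"MGF block {idx}: invalid peak list")
    peaks = merge_close_peaks(
        (Peak(float(m), float(i)) for m, i in zip(mzs, ints)), merge_tol
    )
    return Spectrum(
        id=title,
        precursor_mz=prec_mz,
        charge=charge,
        rt=rt_min,
        peaks=peaks,
        precursor_intensity=prec_int,
    )


def write_mgf(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as MGF (BEGIN IONS / PEPMASS / CHARGE /
    RTINSECONDS / TITLE blocks), round-trippable by :func:`read_mgf`."""
    path = Path(path)
    entries = []
    for s in dataset:
        params: dict = {"title": s.id}
        if s.precursor_intensity is not None:
            params["pepmass"] = (s.precursor_mz, s.precursor_intensity)
        else:
            params["pepmass"] = s.precursor_mz
        params["charge"] = s.charge
        if s.rt is not None:
            params["rtinseconds"] = s.rt * 60.0
        entries.append(
            {
                "params": params,
                "m/z array": [p.mz for p in s.peaks],
                "intensity array": [p.intensity for p in s.peaks],
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
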